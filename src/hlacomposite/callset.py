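"""Container for genotype calls across samples, genotypers, and loci."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .hla_model import LocusGenotype

__all__ = ["GenotypeCallset"]


@dataclass
class GenotypeCallset:
    """sample x genotyper x locus -> :class:`LocusGenotype`.

    Missing keys mean the genotyper produced no call there; :meth:`get`
    returns an empty genotype in that case so concordance code can score
    absent predictions uniformly.
    """

    calls: dict[tuple[str, str, str], LocusGenotype] = field(default_factory=dict)

    def set(self, sample_id: str, genotyper: str, locus: str, gt: LocusGenotype) -> None:
        if gt.locus != locus:
            raise ValueError(f"genotype locus {gt.locus} != key locus {locus}")
        self.calls[(sample_id, genotyper, locus)] = gt

    def get(self, sample_id: str, genotyper: str, locus: str) -> LocusGenotype:
        return self.calls.get((sample_id, genotyper, locus), LocusGenotype(locus=locus))

    def has_call(self, sample_id: str, genotyper: str, locus: str) -> bool:
        gt = self.calls.get((sample_id, genotyper, locus))
        return gt is not None and not gt.is_empty

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(sorted({k[0] for k in self.calls}))

    @property
    def genotypers(self) -> tuple[str, ...]:
        return tuple(sorted({k[1] for k in self.calls}))

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(sorted({k[2] for k in self.calls}))

    def loci_of(self, genotyper: str) -> tuple[str, ...]:
        """Loci for which this genotyper emitted at least one non-empty call."""
        return tuple(
            sorted(
                {
                    k[2]
                    for k, gt in self.calls.items()
                    if k[1] == genotyper and not gt.is_empty
                }
            )
        )

    def subset_genotyper(self, genotyper: str) -> "GenotypeCallset":
        return GenotypeCallset(
            calls={k: v for k, v in self.calls.items() if k[1] == genotyper}
        )

    def items(self) -> Iterator[tuple[tuple[str, str, str], LocusGenotype]]:
        return iter(self.calls.items())

    def __len__(self) -> int:
        return len(self.calls)

    def merge(self, other: "GenotypeCallset") -> "GenotypeCallset":
        """Union of two callsets; duplicate keys are an error."""
        dup = set(self.calls) & set(other.calls)
        if dup:
            raise ValueError(f"duplicate calls on merge: {sorted(dup)[:3]} ...")
        merged = dict(self.calls)
        merged.update(other.calls)
        return GenotypeCallset(calls=merged)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str, LocusGenotype]]
    ) -> "GenotypeCallset":
        cs = cls()
        for sample_id, genotyper, locus, gt in records:
            key = (sample_id, genotyper, locus)
            if key in cs.calls:
                raise ValueError(f"duplicate call for {key}")
            cs.set(sample_id, genotyper, locus, gt)
        return cs
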