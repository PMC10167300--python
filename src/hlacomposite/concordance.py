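"""Genotype concordance metrics: success, accuracy, and agreement.

Two complementary metrics compare a predicted genotype with molecular
ground truth at a fixed field resolution:

* ``success = correct / (correct + incorrect)`` scores only what the
  genotyper called, ignoring missing predictions; it is undefined when
  no alleles were called at the locus.
* ``accuracy = correct / (correct + incorrect + absent)`` additionally
  penalizes failed predictions (a Bray-Curtis-style similarity). For a
  diploid locus it takes values in {0.0, 0.5, 1.0} — 0, 1, or 2 correct
  alleles out of 2.

"Correct" is decided by a maximum-cardinality one-to-one matching of
predicted against ground-truth allele slots, so a homozygous truth
{X, X} met by a single prediction {X} yields one correct and one absent
slot (accuracy 0.5). Agreement between two *predicted* genotypes is
accuracy with the second prediction playing the truth role.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import pandas as pd

from .callset import GenotypeCallset
from .hla_model import LocusGenotype, alleles_match

__all__ = [
    "ConcordanceResult",
    "count_correct",
    "locus_success",
    "locus_accuracy",
    "genotype_agreement",
    "expected_agreement",
    "summarize_concordance",
    "mean_overall_accuracy",
]


@dataclass(frozen=True)
class ConcordanceResult:
    """Allele-slot tallies for one sample x locus x field-level comparison."""

    sample_id: str
    locus: str
    field_level: int
    n_correct: int
    n_incorrect: int
    n_absent: int

    @property
    def success(self) -> float | None:
        """correct/(correct+incorrect); None when nothing was predicted."""
        denom = self.n_correct + self.n_incorrect
        if denom == 0:
            return None
        return self.n_correct / denom

    @property
    def accuracy(self) -> float:
        """correct/(correct+incorrect+absent); 0 for a fully absent call."""
        denom = self.n_correct + self.n_incorrect + self.n_absent
        if denom == 0:
            raise ValueError("accuracy undefined for empty ground truth")
        return self.n_correct / denom


def count_correct(
    truth: LocusGenotype,
    pred: LocusGenotype,
    field_level: int,
    *,
    require_full_depth: bool = True,
) -> tuple[int, int, int]:
    """Tally (correct, incorrect, absent) allele slots at a field level.

    Uses a maximum-cardinality one-to-one assignment between predicted
    alleles and ground-truth slots under :func:`alleles_match`, found by
    exhaustive enumeration (genotypes hold at most a handful of alleles).
    Every unmatched prediction is incorrect; a truth slot is absent only
    when no prediction occupies it (a wrong prediction fills a slot as
    incorrect, it does not additionally create an absence). The tally
    therefore sums to max(#pred, #truth) and diploid accuracy takes only
    the values {0, 0.5, 1}.
    """
    if truth.locus != pred.locus:
        raise ValueError(f"locus mismatch: truth {truth.locus} vs pred {pred.locus}")
    if truth.is_empty:
        raise ValueError("ground-truth genotype must be non-empty")
    t = truth.alleles
    p = pred.alleles
    if not p:
        return 0, 0, len(t)
    # enumerate injective assignments of the smaller side into the larger
    small, large = (p, t) if len(p) <= len(t) else (t, p)
    best = 0
    for assignment in itertools.permutations(range(len(large)), len(small)):
        hits = sum(
            alleles_match(
                small[i], large[j], field_level, require_full_depth=require_full_depth
            )
            for i, j in enumerate(assignment)
        )
        best = max(best, hits)
        if best == len(small):
            break
    return best, len(p) - best, max(0, len(t) - len(p))


def locus_success(result: ConcordanceResult) -> float | None:
    """Proportional match ignoring missing predictions (None if no call)."""
    return result.success


def locus_accuracy(result: ConcordanceResult) -> float:
    """Proportional match penalizing missing predictions."""
    return result.accuracy


def genotype_agreement(
    pred1: LocusGenotype, pred2: LocusGenotype, field_level: int
) -> float:
    """Accuracy of one predicted genotype against another.

    Symmetric for equal-length calls. Two empty calls carry no alleles to
    compare, so the value is NaN (excluded from averages); an empty call
    against a non-empty one scores 0.
    """
    if pred1.locus != pred2.locus:
        raise ValueError("agreement requires a shared locus")
    if pred1.is_empty and pred2.is_empty:
        return math.nan
    if pred2.is_empty:
        # swap so the non-empty call plays the truth role
        pred1, pred2 = pred2, pred1
    n_correct, n_incorrect, n_absent = count_correct(pred2, pred1, field_level)
    return n_correct / (n_correct + n_incorrect + n_absent)


def expected_agreement(acc1: float, acc2: float) -> float:
    """Agreement expected between two independent predictions, the product
    of their accuracies against the shared ground truth."""
    for a in (acc1, acc2):
        if not 0.0 <= a <= 1.0:
            raise ValueError("accuracies must lie in [0, 1]")
    return acc1 * acc2


def concordance_table(
    callset: GenotypeCallset,
    truth: GenotypeCallset,
    field_levels: list[int],
    *,
    truth_genotyper: str = "truth",
    require_full_depth: bool = True,
) -> pd.DataFrame:
    """Per sample x genotyper x locus x field tallies against ground truth.

    Loci a genotyper never assesses (no non-empty call in any sample) are
    omitted rather than scored 0, so means are not deflated by a tool's
    repertoire.
    """
    shared = set(callset.samples) & {k[0] for k in truth.calls}
    if not shared:
        raise ValueError("no overlapping samples between callset and truth")
    rows = []
    for genotyper in callset.genotypers:
        assessed = set(callset.loci_of(genotyper))
        for sample_id in sorted(shared):
            for locus in truth.loci:
                if locus not in assessed:
                    continue
                t = truth.get(sample_id, truth_genotyper, locus)
                if t.is_empty:
                    continue
                p = callset.get(sample_id, genotyper, locus)
                for level in field_levels:
                    nc, ni, na = count_correct(
                        t, p, level, require_full_depth=require_full_depth
                    )
                    res = ConcordanceResult(sample_id, locus, level, nc, ni, na)
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "genotyper": genotyper,
                            "locus": locus,
                            "field_level": level,
                            "n_correct": nc,
                            "n_incorrect": ni,
                            "n_absent": na,
                            "success": math.nan if res.success is None else res.success,
                            "accuracy": res.accuracy,
                        }
                    )
    return pd.DataFrame(rows)


def summarize_concordance(
    callset: GenotypeCallset,
    truth: GenotypeCallset,
    field_levels: list[int],
    *,
    truth_genotyper: str = "truth",
    require_full_depth: bool = True,
) -> pd.DataFrame:
    """Mean success and accuracy per genotyper x locus x field level.

    Tidy output with columns (genotyper, locus, field_level, metric,
    value, n_samples). Means are unweighted over samples; undefined
    success values (no prediction at all) are excluded from the success
    mean rather than imputed. Not-assessed genotyper x locus cells are
    absent from the table.
    """
    per_sample = concordance_table(
        callset,
        truth,
        field_levels,
        truth_genotyper=truth_genotyper,
        require_full_depth=require_full_depth,
    )
    if per_sample.empty:
        return pd.DataFrame(
            columns=["genotyper", "locus", "field_level", "metric", "value", "n_samples"]
        )
    keys = ["genotyper", "locus", "field_level"]
    out = []
    for metric in ("success", "accuracy"):
        grp = per_sample.groupby(keys)[metric].agg(["mean", "count"]).reset_index()
        grp["metric"] = metric
        grp = grp.rename(columns={"mean": "value", "count": "n_samples"})
        out.append(grp[keys + ["metric", "value", "n_samples"]])
    return pd.concat(out, ignore_index=True).sort_values(
        keys + ["metric"], ignore_index=True
    )


def mean_overall_accuracy(
    summary: pd.DataFrame,
    genotyper: str,
    field_level: int,
    *,
    all_loci: list[str] | None = None,
    score_unassessed_zero: bool = False,
) -> float:
    """Mean accuracy for one genotyper across loci at one field level.

    By default loci the genotyper does not assess are excluded from the
    mean; with ``score_unassessed_zero`` they contribute 0 for every locus
    in ``all_loci`` (which is then required).
    """
    sel = summary[
        (summary["genotyper"] == genotyper)
        & (summary["field_level"] == field_level)
        & (summary["metric"] == "accuracy")
    ]
    values = list(sel["value"])
    if score_unassessed_zero:
        if all_loci is None:
            raise ValueError("all_loci required when scoring unassessed loci as zero")
        missing = set(all_loci) - set(sel["locus"])
        values.extend(0.0 for _ in missing)
    if not values:
        raise ValueError(f"no assessed loci for genotyper {genotyper!r}")
    return float(sum(values) / len(values))
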