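"""Synthetic cohorts with known ground truth for every pipeline stage.

Emulates the input shapes of a pseudobulk scRNA-seq HLA genotyping
study: diploid genotypes with DRB1 <-> DRB3/4/5 haplotype linkage, noisy
genotyper callsets with configurable per-field substitution and dropout,
copy-number-proportional DRB read counts with overdispersed noise,
skewed per-cell biallelic counts for ASE, and a toy alignment with a
high-diversity 5' block. Allele names are generated inside the IMGT
grammar (e.g. ``A*90:01:02``) without shipping any real allele database,
and the DRB1-group -> paralog linkage table is a deliberately simplified
emulation of the real haplotype structure — enough to produce valid
copy-number vectors, not a population-genetics model.

All randomness flows from the config's single seed through per-stage
``numpy.random.SeedSequence`` children, so an identical config gives
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .callset import GenotypeCallset
from .hla_model import CLASSICAL_LOCI, DRB_PARALOGS, HlaAllele, LocusGenotype

__all__ = [
    "GenotyperProfile",
    "SimulationConfig",
    "simulate_cohort",
    "simulate_callset",
    "simulate_read_counts",
    "simulate_cell_counts",
    "simulate_alignment",
    "simulate_study",
    "DRB1_LINKAGE",
]

#: DRB1 allele-group -> linked paralog (simplified haplotype table).
#: Real DRB1 lineages segregate with at most one functional paralog per
#: haplotype; the group identities here mirror the broad pattern only.
DRB1_LINKAGE: dict[str, str | None] = {
    "01": None,
    "08": None,
    "10": None,
    "03": "DRB3",
    "11": "DRB3",
    "12": "DRB3",
    "13": "DRB3",
    "14": "DRB3",
    "04": "DRB4",
    "07": "DRB4",
    "09": "DRB4",
    "15": "DRB5",
    "16": "DRB5",
}

_STAGES = ("cohort", "callset", "reads", "cells", "alignment")


@dataclass
class GenotyperProfile:
    """Error model for one simulated genotyper.

    ``field_substitution`` maps field level -> probability that the field
    at that level is replaced (a field-2 error keeps field 1; a field-1
    error re-draws the allele group). ``dropout`` is the per-allele
    probability of dropping a call; ``locus_dropout`` optionally
    overrides it per locus. ``max_fields`` truncates emitted calls (a
    2-field-only tool). ``spurious_drb345_rate`` adds an extra unlinked
    paralog allele to exercise top-n copy-number filtering; spurious
    alleles rank after true-derived ones.
    """

    name: str
    field_substitution: dict[int, float] = field(default_factory=dict)
    dropout: float = 0.0
    locus_dropout: dict[str, float] = field(default_factory=dict)
    max_fields: int = 3
    spurious_drb345_rate: float = 0.0
    loci: tuple[str, ...] | None = None  # None = assesses everything

    def dropout_for(self, locus: str) -> float:
        return self.locus_dropout.get(locus, self.dropout)


def _default_genotypers() -> list[GenotyperProfile]:
    # Four tools spanning the observed quality range: an accurate
    # class-II-strong tool with spurious DRB345 extras, an accurate
    # class-I-only tool with occasional whole-call failures, a mid-range
    # tool lacking DP, and a noisy tool.
    return [
        GenotyperProfile(
            name="simA",
            field_substitution={1: 0.03, 2: 0.10, 3: 0.15},
            dropout=0.02,
            spurious_drb345_rate=0.6,
        ),
        GenotyperProfile(
            name="simB",
            field_substitution={1: 0.02, 2: 0.05, 3: 0.10},
            dropout=0.08,
            max_fields=2,
            loci=("A", "B", "C"),
        ),
        GenotyperProfile(
            name="simC",
            field_substitution={1: 0.05, 2: 0.15, 3: 0.25},
            dropout=0.05,
            loci=tuple(l for l in CLASSICAL_LOCI if l not in ("DPA1", "DPB1"))
            + DRB_PARALOGS,
        ),
        GenotyperProfile(
            name="simD",
            field_substitution={1: 0.25, 2: 0.40, 3: 0.50},
            dropout=0.15,
            spurious_drb345_rate=0.8,
        ),
    ]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate a mid-sized 5' scRNA-seq cohort: 150 diploid
    samples, four genotypers of graded quality, DRB read depth with
    gamma-Poisson overdispersion, per-copy DRB ratio 0.45 with Gaussian
    noise sigma 0.05, and per-cell ASE counts with ~20 reads per cell.
    """

    seed: int
    n_samples: int = 150
    alleles_per_locus: int = 12
    truth_fields: int = 3
    genotypers: list[GenotyperProfile] = field(default_factory=_default_genotypers)
    # read-depth model
    drb1_mean_reads: float = 200.0
    drb1_dispersion: float = 0.3  # gamma CV^2 of the Poisson mean; 0 = Poisson-free deterministic
    per_copy_ratio: float = 0.45
    ratio_sigma: float = 0.05
    # ASE model
    ase_mu: float = float(np.log(3.0))
    ase_tau2: float = 0.0
    ase_n_cells: int = 200
    ase_reads_per_cell: float = 20.0
    ase_groups: tuple[str, ...] = ("g1",)
    # toy alignment
    msa_n_sequences: int = 12
    msa_length: int = 600
    msa_variable_prefix: int = 200

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for p in self.genotypers:
            rates = [p.dropout, p.spurious_drb345_rate, *p.field_substitution.values(),
                     *p.locus_dropout.values()]
            if any(not 0 <= r <= 1 for r in rates):
                raise ValueError(f"genotyper {p.name}: rates must lie in [0, 1]")

    def stage_rng(self, stage: str) -> np.random.Generator:
        """Independent generator for one stage, derived from the seed."""
        idx = _STAGES.index(stage)
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGES))
        return np.random.default_rng(children[idx])


def _allele(rng: np.random.Generator, locus: str, group: str, n_fields: int) -> HlaAllele:
    fields = [group]
    for _ in range(n_fields - 1):
        fields.append(f"{rng.integers(1, 100):02d}")
    return HlaAllele(locus=locus, fields=tuple(fields[:n_fields]))


def _locus_pool(
    rng: np.random.Generator, locus: str, n_alleles: int, n_fields: int
) -> tuple[list[HlaAllele], np.ndarray]:
    """Frequency-weighted synthetic allele pool for one locus."""
    groups = rng.choice(np.arange(90, 100), size=min(n_alleles, 10), replace=False)
    pool = []
    for g in groups:
        pool.append(_allele(rng, locus, f"{g:02d}", n_fields))
    freqs = rng.dirichlet(np.full(len(pool), 2.0))
    return pool, freqs


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[GenotypeCallset, pd.DataFrame]:
    """Ground-truth genotypes plus DRB copy-number vectors.

    Each sample draws two haplotypes; a haplotype carries one DRB1 allele
    whose group determines the linked paralog (or none) via
    :data:`DRB1_LINKAGE`, so drb3+drb4+drb5 <= 2 by construction.
    Classical loci draw two alleles each from frequency-weighted pools.
    """
    if config.alleles_per_locus < 1:
        raise ValueError("allele pool must be non-empty")
    rng = config.stage_rng("cohort")
    truth = GenotypeCallset()
    pools = {
        locus: _locus_pool(rng, locus, config.alleles_per_locus, config.truth_fields)
        for locus in CLASSICAL_LOCI
        if locus != "DRB1"
    }
    drb1_groups = list(DRB1_LINKAGE)
    drb1_freqs = rng.dirichlet(np.full(len(drb1_groups), 2.0))
    paralog_pools = {
        p: _locus_pool(rng, p, max(3, config.alleles_per_locus // 3), config.truth_fields)
        for p in DRB_PARALOGS
    }
    cn_rows = []
    for i in range(config.n_samples):
        sample_id = f"S{i:04d}"
        for locus, (pool, freqs) in pools.items():
            picks = rng.choice(len(pool), size=2, p=freqs)
            truth.set(
                sample_id,
                "truth",
                locus,
                LocusGenotype(locus=locus, alleles=tuple(pool[j] for j in picks)),
            )
        # two DRB haplotypes with linkage
        drb1_alleles: list[HlaAllele] = []
        paralog_alleles: dict[str, list[HlaAllele]] = {p: [] for p in DRB_PARALOGS}
        cn = dict.fromkeys(DRB_PARALOGS, 0)
        for _ in range(2):
            group = drb1_groups[rng.choice(len(drb1_groups), p=drb1_freqs)]
            drb1_alleles.append(_allele(rng, "DRB1", group, config.truth_fields))
            linked = DRB1_LINKAGE[group]
            if linked is not None:
                pool, freqs = paralog_pools[linked]
                paralog_alleles[linked].append(pool[rng.choice(len(pool), p=freqs)])
                cn[linked] += 1
        truth.set(
            sample_id,
            "truth",
            "DRB1",
            LocusGenotype(locus="DRB1", alleles=tuple(drb1_alleles)),
        )
        for p in DRB_PARALOGS:
            if paralog_alleles[p]:
                truth.set(
                    sample_id,
                    "truth",
                    p,
                    LocusGenotype(locus=p, alleles=tuple(paralog_alleles[p])),
                )
        cn_rows.append(
            {
                "sample_id": sample_id,
                "drb3": cn["DRB3"],
                "drb4": cn["DRB4"],
                "drb5": cn["DRB5"],
            }
        )
    copy_numbers = pd.DataFrame(cn_rows).set_index("sample_id")
    return truth, copy_numbers


def _substitute(
    rng: np.random.Generator, allele: HlaAllele, profile: GenotyperProfile
) -> HlaAllele:
    fields = list(allele.fields)
    for level in range(1, len(fields) + 1):
        rate = profile.field_substitution.get(level, 0.0)
        if rate > 0 and rng.random() < rate:
            old = fields[level - 1]
            new = old
            while new == old:
                new = f"{rng.integers(1, 100):02d}"
            fields[level - 1] = new
            # an error at level f makes deeper fields meaningless noise too;
            # keep them as drawn-anew values
            for deeper in range(level, len(fields)):
                fields[deeper] = f"{rng.integers(1, 100):02d}"
            break
    return HlaAllele(locus=allele.locus, fields=tuple(fields))


def simulate_callset(
    truth: GenotypeCallset, config: SimulationConfig
) -> GenotypeCallset:
    """Noisy genotyper callsets derived from the ground truth.

    Per genotyper x locus x allele: drop with the dropout probability,
    otherwise substitute fields per the profile and truncate to the
    tool's field depth. DRB345 calls may gain a spurious extra paralog
    allele; emitted rank order is true-derived alleles first, spurious
    after, so top-n filtering has a meaningful ranking to cut.
    """
    rng = config.stage_rng("callset")
    out = GenotypeCallset()
    samples = truth.samples
    for profile in config.genotypers:
        for sample_id in samples:
            spurious_targets: list[str] = []
            if profile.spurious_drb345_rate > 0 and rng.random() < profile.spurious_drb345_rate:
                spurious_targets = [DRB_PARALOGS[rng.integers(0, len(DRB_PARALOGS))]]
            for locus in truth.loci:
                if profile.loci is not None and locus not in profile.loci:
                    continue
                t = truth.get(sample_id, "truth", locus)
                kept: list[HlaAllele] = []
                for allele in t.alleles:
                    if rng.random() < profile.dropout_for(locus):
                        continue
                    noisy = _substitute(rng, allele, profile)
                    kept.append(
                        HlaAllele(
                            locus=locus,
                            fields=noisy.fields[: profile.max_fields],
                        )
                    )
                is_drb = locus in DRB_PARALOGS
                if is_drb and locus in spurious_targets:
                    group = f"{rng.integers(90, 100):02d}"
                    kept.append(_allele(rng, locus, group, profile.max_fields))
                if kept or not t.is_empty:
                    out.set(
                        sample_id,
                        profile.name,
                        locus,
                        LocusGenotype(locus=locus, alleles=tuple(kept), ranked=is_drb),
                    )
    return out


def simulate_read_counts(
    copy_numbers: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Locus-level mapped-read counts carrying the copy-number signal.

    DRB1 reads follow a gamma-Poisson (negative-binomial-like) model with
    mean ``drb1_mean_reads``; zero dispersion gives deterministic counts.
    Each paralog's reads are DRB1 reads times
    ``copy_number * per_copy_ratio`` plus Gaussian ratio noise, clipped
    at zero — so the realized paralog/DRB1 ratios have class-conditional
    means {0, 0.45, 0.9} by default.
    """
    rng = config.stage_rng("reads")
    rows = []
    for sample_id, row in copy_numbers.iterrows():
        if config.drb1_dispersion > 0:
            shape = 1.0 / config.drb1_dispersion
            lam = rng.gamma(shape, config.drb1_mean_reads / shape)
            drb1 = int(rng.poisson(lam))
        else:
            drb1 = int(round(config.drb1_mean_reads))
        rows.append({"sample_id": sample_id, "locus": "DRB1", "reads": drb1})
        for paralog in DRB_PARALOGS:
            cn = int(row[paralog.lower()])
            ratio = cn * config.per_copy_ratio
            if config.ratio_sigma > 0:
                ratio += rng.normal(0.0, config.ratio_sigma)
            reads = int(round(max(0.0, ratio) * drb1))
            rows.append({"sample_id": sample_id, "locus": paralog, "reads": reads})
    return pd.DataFrame(rows)


def simulate_cell_counts(config: SimulationConfig) -> pd.DataFrame:
    """Per-cell biallelic counts with a planted ASE effect.

    Per cell: true log-odds theta ~ Normal(mu, tau^2); total reads
    T ~ 1 + Poisson(reads_per_cell - 1) (so every cell has at least one
    read); allele-1 count ~ Binomial(T, logistic(theta)). One block per
    configured group, all sharing mu and tau^2 unless the caller builds
    several configs.
    """
    rng = config.stage_rng("cells")
    rows = []
    for group in config.ase_groups:
        if config.ase_tau2 < 0:
            raise ValueError("ase_tau2 must be nonnegative")
        theta = rng.normal(
            config.ase_mu, math.sqrt(config.ase_tau2), size=config.ase_n_cells
        )
        totals = 1 + rng.poisson(max(0.0, config.ase_reads_per_cell - 1),
                                 size=config.ase_n_cells)
        p = 1.0 / (1.0 + np.exp(-theta))
        c1 = rng.binomial(totals, p)
        for i in range(config.ase_n_cells):
            rows.append(
                {
                    "cell_id": f"{group}_c{i:05d}",
                    "group": group,
                    "count_allele1": int(c1[i]),
                    "count_allele2": int(totals[i] - c1[i]),
                }
            )
    return pd.DataFrame(rows)


def simulate_alignment(config: SimulationConfig) -> list[tuple[str, str]]:
    """Toy aligned allele set: variable 5' block, conserved remainder.

    Mirrors the shape of real HLA diversity profiles, where polymorphism
    concentrates toward the 5' end of each gene. Returns (name, sequence)
    pairs of equal length; a sprinkling of gap columns in the conserved
    tail exercises gap handling.
    """
    rng = config.stage_rng("alignment")
    bases = np.array(list("ACGT"))
    backbone = rng.integers(0, 4, size=config.msa_length)
    records = []
    for i in range(config.msa_n_sequences):
        seq = backbone.copy()
        var = rng.integers(0, 4, size=config.msa_variable_prefix)
        seq[: config.msa_variable_prefix] = var
        chars = bases[seq].copy()
        # partial 3' coverage for some alleles, as in published references
        if i % 4 == 3:
            tail = rng.integers(config.msa_length - 50, config.msa_length)
            chars[tail:] = "-"
        records.append((f"SYN*{90 + i % 10:02d}:{i + 1:02d}", "".join(chars)))
    return records


def simulate_study(config: SimulationConfig) -> dict:
    """Run every generator once and bundle the results.

    Returns a dict with keys ``truth`` (GenotypeCallset),
    ``copy_numbers`` (DataFrame), ``calls`` (GenotypeCallset),
    ``read_counts``, ``cell_counts`` (DataFrames), ``alignment``
    ((name, seq) pairs), and ``config``.
    """
    truth, copy_numbers = simulate_cohort(config)
    calls = simulate_callset(truth, config)
    read_counts = simulate_read_counts(copy_numbers, config)
    cell_counts = simulate_cell_counts(config)
    alignment = simulate_alignment(config)
    return {
        "truth": truth,
        "copy_numbers": copy_numbers,
        "calls": calls,
        "read_counts": read_counts,
        "cell_counts": cell_counts,
        "alignment": alignment,
        "config": config,
    }
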