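"""Readers and writers for the pipeline's table and sequence formats.

Canonical tables are tab-delimited (allele names never contain tabs),
UTF-8, Unix newlines. The genotype table schema is::

    sample_id  genotyper  locus  allele1  allele2 [allele3 ...]

Empty cells mean no call; extra alleleN columns hold unfiltered DRB345
calls whose column order is the upstream rank. Alignments are plain
(aligned) FASTA via Biopython.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .callset import GenotypeCallset
from .hla_model import AlleleParseError, LocusGenotype, parse_allele

__all__ = [
    "read_genotype_table",
    "write_genotype_table",
    "read_read_counts",
    "write_read_counts",
    "read_cell_counts",
    "write_cell_counts",
    "read_alignment_fasta",
    "write_alignment_fasta",
    "load_config_yaml",
    "write_manifest",
]

_KNOWN_LOCI = {
    "A", "B", "C", "DRB1", "DRB3", "DRB4", "DRB5",
    "DQA1", "DQB1", "DPA1", "DPB1",
}


def read_genotype_table(path: str | Path, *, ranked_loci: set[str] | None = None) -> GenotypeCallset:
    """Read a genotype TSV into a :class:`GenotypeCallset`.

    Allele strings are validated on the way in; a malformed allele or an
    unknown locus token raises with the 1-based data row number.
    Duplicate sample x genotyper x locus rows are ambiguous and rejected.
    ``ranked_loci`` marks loci whose column order is a confidence ranking
    (defaults to the DRB paralogs).
    """
    ranked_loci = ranked_loci if ranked_loci is not None else {"DRB3", "DRB4", "DRB5"}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_id", "genotyper", "locus"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    allele_cols = [c for c in df.columns if c.startswith("allele")]
    if not allele_cols:
        raise ValueError(f"{path}: no alleleN columns")
    allele_cols.sort(key=lambda c: int(c.removeprefix("allele")))
    cs = GenotypeCallset()
    for rownum, row in enumerate(df.itertuples(index=False), start=1):
        locus = getattr(row, "locus")
        if locus not in _KNOWN_LOCI:
            raise ValueError(f"{path}: row {rownum}: unknown locus {locus!r}")
        alleles = []
        for col in allele_cols:
            cell = getattr(row, col).strip()
            if not cell:
                continue
            try:
                alleles.append(parse_allele(cell))
            except AlleleParseError as exc:
                raise ValueError(f"{path}: row {rownum}: {exc}") from exc
        key = (row.sample_id, row.genotyper, locus)
        if key in cs.calls:
            raise ValueError(
                f"{path}: row {rownum}: duplicate call for sample {row.sample_id!r}, "
                f"genotyper {row.genotyper!r}, locus {locus!r}"
            )
        cs.set(
            row.sample_id,
            row.genotyper,
            locus,
            LocusGenotype(
                locus=locus, alleles=tuple(alleles), ranked=locus in ranked_loci
            ),
        )
    return cs


def write_genotype_table(callset: GenotypeCallset, path: str | Path) -> None:
    """Write a callset as a genotype TSV (sorted keys, rank-order columns)."""
    max_alleles = max((len(gt) for gt in callset.calls.values()), default=0)
    n_cols = max(2, max_alleles)
    rows = []
    for (sample_id, genotyper, locus), gt in sorted(callset.calls.items()):
        row = {"sample_id": sample_id, "genotyper": genotyper, "locus": locus}
        for i in range(n_cols):
            row[f"allele{i + 1}"] = str(gt.alleles[i]) if i < len(gt) else ""
        rows.append(row)
    cols = ["sample_id", "genotyper", "locus"] + [f"allele{i + 1}" for i in range(n_cols)]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_read_counts(path: str | Path) -> pd.DataFrame:
    """Long locus read-count table: sample_id, locus, reads (int)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "locus": str})
    missing = [c for c in ("sample_id", "locus", "reads") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["reads"] = df["reads"].astype(int)
    return df


def write_read_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_cell_counts(path: str | Path) -> pd.DataFrame:
    """Per-cell biallelic counts: cell_id, group, count_allele1, count_allele2."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "group": str})
    missing = [
        c
        for c in ("cell_id", "count_allele1", "count_allele2")
        if c not in df.columns
    ]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for c in ("count_allele1", "count_allele2"):
        df[c] = df[c].astype(int)
    return df


def write_cell_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_alignment_fasta(path: str | Path) -> list[SeqRecord]:
    """Aligned FASTA; raises on ragged sequence lengths."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if records and len({len(r.seq) for r in records}) != 1:
        raise ValueError(f"{path}: sequences are not aligned (unequal lengths)")
    return records


def write_alignment_fasta(records, path: str | Path) -> None:
    """Write (name, sequence) pairs or SeqRecords as FASTA."""
    out = []
    for rec in records:
        if isinstance(rec, SeqRecord):
            out.append(rec)
        else:
            name, seq = rec
            out.append(SeqRecord(Seq(seq), id=name, description=""))
    SeqIO.write(out, str(path), "fasta")


def load_config_yaml(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def config_hash(config: dict) -> str:
    """Stable sha256 of a config mapping (sorted-key JSON)."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


def write_manifest(outdir: str | Path, config: dict, stages: list[str], seed: int) -> Path:
    """Machine-readable run manifest: config hash, seed, stage list."""
    import hlacomposite

    manifest = {
        "package": "hlacomposite",
        "version": getattr(hlacomposite, "__version__", "unknown"),
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
        "stages": stages,
    }
    path = Path(outdir) / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
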