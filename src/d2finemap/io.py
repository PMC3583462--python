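"""Readers, writers and packaged fixtures.

All tables are UTF-8 TSV with ``NA`` (genotypes, counts) or ``ND`` (allele
matrices) as missing sentinels.  A genotype table carries a second header
line declaring each locus' scoring mode::

    plant_id<TAB>B224C4P2<TAB>Ca_Sb07g023840
    #mode<TAB>codominant<TAB>dominant
    p0001<TAB>AA<TAB>A-

Every writer round-trips losslessly through its reader.
"""
from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .haplotype_scan import HaplotypeMatrix, BlockResult
from .linkage import GenotypeTable
from .progeny_test import F3Family, TraitCall
from .synteny import ANCHOR_COLUMNS, CandidateInterval, SyntenyBlock

NA = "NA"


# ---------------------------------------------------------------------------
# genotype tables
# ---------------------------------------------------------------------------

def read_genotype_table(path) -> GenotypeTable:
    """Read a plants x loci TSV whose second line declares locus modes."""
    path = Path(path)
    text = path.read_text(encoding="utf-8").splitlines()
    if not text or not text[0].strip():
        raise ValueError(f"{path}: empty genotype table")
    header = text[0].rstrip("\n").split("\t")
    if len(text) < 2 or not text[1].startswith("#mode"):
        raise ValueError(f"{path}: missing '#mode' header line")
    modes_row = text[1].split("\t")
    loci = header[1:]
    modes = dict(zip(loci, modes_row[1:]))
    rows, index = [], []
    for lineno, line in enumerate(text[2:], start=3):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ValueError(f"{path}:{lineno}: expected {len(header)} "
                             f"fields, got {len(fields)}")
        index.append(fields[0])
        rows.append(fields[1:])
    if not rows:
        raise ValueError(f"{path}: no plants in genotype table")
    calls = pd.DataFrame(rows, index=index, columns=loci)
    try:
        return GenotypeTable(calls, modes)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err


def write_genotype_table(table: GenotypeTable, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("plant_id\t" + "\t".join(table.loci) + "\n")
        fh.write("#mode\t" + "\t".join(table.modes[l] for l in table.loci)
                 + "\n")
        for plant, row in table.calls.iterrows():
            fh.write(str(plant) + "\t" + "\t".join(row) + "\n")


def read_trait_truth(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return pd.Series(df["trait_genotype"].values, index=df["plant_id"],
                     name="trait_genotype")


def write_trait_truth(truth: pd.Series, path) -> None:
    pd.DataFrame({"plant_id": truth.index, "trait_genotype": truth.values}
                 ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# F3 families
# ---------------------------------------------------------------------------

def read_heights_table(path) -> list[F3Family]:
    """Per-plant heights TSV (f2_id, plant_id, batch, height_cm) -> families."""
    df = pd.read_csv(path, sep="\t", dtype={"f2_id": str, "batch": str})
    families = []
    for (fid, batch), sub in df.groupby(["f2_id", "batch"], sort=False):
        families.append(F3Family(f2_id=str(fid), batch=str(batch),
                                 heights=list(sub["height_cm"].astype(float))))
    return families


def write_heights_table(families: list[F3Family], path) -> None:
    rows = []
    for fam in families:
        for i, h in enumerate(fam.heights or []):
            rows.append({"f2_id": fam.f2_id, "plant_id": f"{fam.f2_id}.{i+1}",
                         "batch": fam.batch, "height_cm": h})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_family_summaries(path) -> list[F3Family]:
    """Pre-summarized families (f2_id, batch, n, median_cm, mean_cm, sd_cm,
    n_below_110); ``NA``/``ND`` mark unavailable values, an all-NA row an
    F2 plant without surviving progeny."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[NA, "ND"])
    families = []
    for _, row in df.iterrows():
        if pd.isna(row.get("n")):
            families.append(F3Family(f2_id=str(row["f2_id"]), n=0))
            continue
        nb = row.get("n_below_110")
        families.append(F3Family(
            f2_id=str(row["f2_id"]),
            batch=str(row["batch"]) if pd.notna(row.get("batch")) else "1",
            n=int(float(row["n"])),
            median_cm=float(row["median_cm"]),
            mean_cm=float(row["mean_cm"]) if pd.notna(row.get("mean_cm"))
            else None,
            sd_cm=float(row["sd_cm"]) if pd.notna(row.get("sd_cm")) else None,
            n_below_cutoff=int(float(nb)) if pd.notna(nb) else None))
    return families


def write_trait_calls(calls: list[TraitCall], path) -> None:
    rows = []
    for c in calls:
        rows.append({"f2_id": c.f2_id, "call": c.call,
                     "chi2_3to1": "" if c.chi2_3to1 is None
                     else f"{c.chi2_3to1:.4f}",
                     "p_value_3to1": "" if c.p_value_3to1 is None
                     else f"{c.p_value_3to1:.4f}",
                     "rule_fired": c.rule_fired, "warning": c.warning})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# haplotype matrices
# ---------------------------------------------------------------------------

def read_haplotype_matrix(path) -> HaplotypeMatrix:
    """Lines x loci TSV with columns ``line``, ``class``, then one per locus."""
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("line")
    classes = df.pop("class")
    return HaplotypeMatrix(df, classes)


def write_haplotype_matrix(matrix: HaplotypeMatrix, path) -> None:
    out = matrix.alleles.copy()
    out.insert(0, "class", matrix.classes)
    out.index.name = "line"
    out.to_csv(path, sep="\t")


def write_locus_verdicts(result: BlockResult, path) -> None:
    rows = []
    for v in result.verdicts:
        rows.append({"locus": v.locus, "status": v.status,
                     "in_block": v.locus in result.block_loci,
                     "dwarf_allele": v.dwarf_allele or "",
                     "exception_lines": ",".join(v.exception_lines)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# anchors, annotation, blocks, BED
# ---------------------------------------------------------------------------

def read_anchor_table(path) -> pd.DataFrame:
    """Tab-separated (gene_a, chr_a, pos_a, gene_b, chr_b, pos_b, evalue)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t",
                         dtype={"chr_a": str, "chr_b": str})
    except Exception as err:
        raise ValueError(f"{path}: malformed anchor table: {err}") from err
    missing = [c for c in ANCHOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: anchor table lacks columns {missing}")
    for col in ("pos_a", "pos_b", "evalue"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            lineno = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
            raise ValueError(f"{path}:{lineno}: non-numeric {col!r}")
        df[col] = pd.to_numeric(df[col])
    return df


def write_anchor_table(anchors: pd.DataFrame, path) -> None:
    anchors.to_csv(path, sep="\t", index=False)


def write_blocks_table(blocks: list[SyntenyBlock], path) -> None:
    rows = []
    for i, b in enumerate(blocks):
        rows.append({"block_id": i, "chr_a": b.chr_a, "chr_b": b.chr_b,
                     "orientation": b.orientation,
                     "score": f"{b.score:.3f}", "n_anchors": len(b),
                     "start_a": b.span_a[0], "end_a": b.span_a[1],
                     "start_b": b.span_b[0], "end_b": b.span_b[1]})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    """Gene annotation as GFF3 (``gene`` features) or 4-column TSV.

    Returns a DataFrame with ``gene_id``, ``chrom``, ``start``, ``end``
    (1-based inclusive, the representative coordinate being ``start``).
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        import gffutils

        db = gffutils.create_db(str(path), ":memory:",
                                merge_strategy="create_unique",
                                keep_order=True)
        rows = [{"gene_id": f.id, "chrom": f.seqid, "start": f.start,
                 "end": f.end} for f in db.features_of_type("gene")]
        return pd.DataFrame(rows)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if "end" not in df.columns:
        df["end"] = df["start"]
    return df[["gene_id", "chrom", "start", "end"]]


def write_bed(interval: CandidateInterval, path) -> None:
    Path(path).write_text(interval.to_bed_row() + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# config, manifest, fixtures
# ---------------------------------------------------------------------------

def read_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        if str(path).endswith(".json"):
            return json.load(fh)
        return yaml.safe_load(fh)


def write_config(config: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if str(path).endswith(".json"):
            json.dump(config, fh, indent=2, sort_keys=True)
        else:
            yaml.safe_dump(config, fh, sort_keys=True)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def fixture_path(name: str) -> Path:
    """Path to a packaged fixture TSV."""
    return Path(resources.files("d2finemap") / "data" / name)


def load_f3_family_fixture() -> list[F3Family]:
    """Summarized F3 families of the dwarf x tall fine-mapping cross
    (one row per phenotyping batch; one F2 plant yielded no progeny data)."""
    return read_family_summaries(fixture_path("f3_family_summaries.tsv"))


def load_haplotype_fixture() -> HaplotypeMatrix:
    """Allele matrix of three tall and three dwarf inbred lines at 12 loci."""
    return read_haplotype_matrix(fixture_path("inbred_haplotypes.tsv"))


def load_genotype_fixture(population: str = "tift") -> GenotypeTable:
    """Synthetic genotype tables for the two informative-plant sets.

    ``"tift"``: 23 informative plants of the dwarf x tall F2 (one crossover
    each between the flanking markers, the trait cosegregating with the
    eight-marker cluster, one double-recombinant trait score).  ``"pt732b"``:
    16 informative plants of the second cross with two marker clusters.
    Both are synthetic reconstructions consistent with the published counts;
    the underlying per-plant data were never published.
    """
    names = {"tift": "synthetic_tift_f2_genotypes.tsv",
             "pt732b": "synthetic_pt732b_f2_genotypes.tsv"}
    return read_genotype_table(fixture_path(names[population]))
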