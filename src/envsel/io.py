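"""Readers and writers for the pipeline's file formats.

All coordinates are 1-based inclusive at file boundaries (VCF/GFF
convention) and converted only here.  Formats: VCF with per-sample GP (or
PL) fields for genotype posteriors, Bismark-style cytosine report TSV,
GFF3 gene/TE annotations, count-matrix TSV, sample-metadata TSV, SFS TSV
and TE insertion tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .sfs import GenotypePosteriors, SFSPair

CYTOSINE_COLUMNS = ["chrom", "pos", "strand", "context", "meth", "total", "individual"]
VALID_CONTEXTS = {"CG", "CHG", "CHH"}


@dataclass
class RunConfig:
    """Analysis thresholds (the published defaults) plus run provenance."""

    min_site_reads: int = 4  # sites with <=3 reads removed
    max_missing: float = 0.5
    min_cytosines: int = 10
    min_median_count: float = 1.0
    q_threshold: float = 0.05
    bonferroni_threshold: float = 0.05
    te_het_low: float = 0.15
    te_het_high: float = 0.85
    te_min_coverage: int = 6
    gene_bootstrap_reps: int = 1000
    sfs_bootstrap_reps: int = 500
    sweep_percentile: float = 99.0
    theta_multiplier: float = 2.76
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        if not 0 < self.max_missing <= 1:
            raise ValueError("max_missing must be in (0, 1]")
        if not 0 <= self.te_het_low <= self.te_het_high <= 1:
            raise ValueError("TE genotype thresholds out of order")
        for name in ("q_threshold", "bonferroni_threshold"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if not 0 < self.sweep_percentile < 100:
            raise ValueError("sweep_percentile must be in (0, 100)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def write_provenance(self, path: str | Path, **extra) -> None:
        from . import __version__

        record = {"config": asdict(self), "version": __version__, **extra}
        Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")


# ---------------------------------------------------------------------------
# VCF genotype posteriors

def write_vcf_gp(gp: GenotypePosteriors, path: str | Path) -> None:
    """Write posteriors as a VCF with a per-sample GP field (plus AA and SC INFO)."""
    inds = gp.individuals["individual"].tolist()
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">',
        '##INFO=<ID=SC,Number=1,Type=String,Description="Site class">',
        '##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype posterior">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(inds),
    ]
    for i, site in enumerate(gp.sites.itertuples()):
        anc = site.ancestral if isinstance(site.ancestral, str) else "."
        info = f"AA={anc};SC={site.site_class}"
        fields = [
            str(site.chrom), str(site.pos), ".", site.ref, site.alt, ".", "PASS",
            info, "GP",
        ]
        for j in range(len(inds)):
            trip = gp.probs[i, j]
            if np.isnan(trip).any():
                fields.append(".")
            else:
                fields.append(",".join(f"{v:.6g}" for v in trip))
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf_posteriors(path: str | Path, metadata: pd.DataFrame) -> GenotypePosteriors:
    """Read genotype posteriors from a VCF (GP preferred, PL converted).

    Multiallelic records are skipped (count in ``attrs``); PL values are
    converted as 10^(-PL/10) and normalized.  ``metadata`` maps individual
    to population (columns ``individual, population``).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    pops = metadata.set_index("individual")["population"]
    missing = [s for s in samples if s not in pops.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    site_rows, prob_rows = [], []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        try:
            gp = var.format("GP")
        except KeyError:
            gp = None
        if gp is None:
            try:
                pl = var.format("PL")
            except KeyError:
                pl = None
            if pl is None:
                raise ValueError(f"record {var.CHROM}:{var.POS} has neither GP nor PL")
            lik = np.power(10.0, -np.asarray(pl, dtype=float) / 10.0)
            gp = lik / lik.sum(axis=1, keepdims=True)
        gp = np.asarray(gp, dtype=float)
        gp = np.where(gp < 0, np.nan, gp)  # cyvcf2 missing sentinel
        info = dict(var.INFO)
        aa = info.get("AA")
        site_rows.append(
            (var.CHROM, var.POS, var.REF, var.ALT[0],
             info.get("SC", "other"), aa if aa not in (None, ".") else None)
        )
        prob_rows.append(gp)
    sites = pd.DataFrame(
        site_rows, columns=["chrom", "pos", "ref", "alt", "site_class", "ancestral"]
    )
    individuals = pd.DataFrame(
        {"individual": samples, "population": [pops[s] for s in samples]}
    )
    probs = (
        np.array(prob_rows) if prob_rows else np.empty((0, len(samples), 3))
    )
    out = GenotypePosteriors(sites=sites, individuals=individuals, probs=probs)
    out.sites.attrs["skipped_multiallelic"] = skipped
    return out


# ---------------------------------------------------------------------------
# cytosine report

def write_cytosine_report(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out["unmeth"] = out["total"] - out["meth"]
    out[["chrom", "pos", "strand", "meth", "unmeth", "context", "individual"]].to_csv(
        path, sep="\t", index=False
    )


def read_cytosine_report(path: str | Path) -> pd.DataFrame:
    """Bismark-dialect cytosine report: chrom, pos, strand, meth, unmeth, context.

    Rejects unknown context tokens and negative counts; returns the
    pipeline's long format with a ``total`` column.  An empty file yields an
    empty table.
    """
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        return pd.DataFrame(columns=CYTOSINE_COLUMNS)
    bad = set(df["context"]) - VALID_CONTEXTS
    if bad:
        raise ValueError(f"unknown context tokens: {sorted(bad)}")
    if (df[["meth", "unmeth"]] < 0).any().any():
        raise ValueError("negative read counts")
    df["total"] = df["meth"] + df["unmeth"]
    if "individual" not in df.columns:
        df["individual"] = "sample1"
    return df[CYTOSINE_COLUMNS]


# ---------------------------------------------------------------------------
# SFS

def write_sfs(sfs: SFSPair, path: str | Path) -> None:
    header = (
        f"#n={sfs.n}\tfolded={int(sfs.folded)}\tL_S={sfs.l_s:.10g}\t"
        f"L_N={sfs.l_n:.10g}\tdS={sfs.d_s:.10g}\tdN={sfs.d_n:.10g}\n"
    )
    body = pd.DataFrame({"bin": np.arange(1, len(sfs.xi_s) + 1),
                         "xi_S": sfs.xi_s, "xi_N": sfs.xi_n})
    with open(path, "w") as fh:
        fh.write(header)
        body.to_csv(fh, sep="\t", index=False)


def read_sfs(path: str | Path) -> SFSPair:
    with open(path) as fh:
        header = fh.readline().lstrip("#").strip()
        meta = dict(item.split("=") for item in header.split("\t"))
        body = pd.read_csv(fh, sep="\t")
    return SFSPair(
        n=int(meta["n"]),
        folded=bool(int(meta["folded"])),
        xi_s=body["xi_S"].to_numpy(float),
        xi_n=body["xi_N"].to_numpy(float),
        l_s=float(meta["L_S"]),
        l_n=float(meta["L_N"]),
        d_s=float(meta["dS"]),
        d_n=float(meta["dN"]),
    )


# ---------------------------------------------------------------------------
# tables

def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_metadata(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"sample", "population", "field"} - set(df.columns)
    if need:
        raise ValueError(f"metadata missing columns: {sorted(need)}")
    return df


def write_te_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_te_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if ((df["support"] < 0) | (df["support"] > 1)).any():
        raise ValueError("read-support proportions must be in [0, 1]")
    return df


# ---------------------------------------------------------------------------
# GFF3

def write_gff3(features: pd.DataFrame, path: str | Path, kind: str = "gene") -> None:
    """Write gene or TE features; family/superfamily/class go into attributes."""
    lines = ["##gff-version 3"]
    for row in features.itertuples():
        attrs = [f"ID={getattr(row, 'gene', None) or getattr(row, 'insertion', None)}"]
        for key in ("family", "superfamily", "te_class"):
            if hasattr(row, key):
                attrs.append(f"{key}={getattr(row, key)}")
        lines.append(
            "\t".join(
                [
                    str(row.chrom), "envsel", kind, str(row.start), str(row.end),
                    ".", getattr(row, "strand", "+"), ".", ";".join(attrs),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read a GFF3 annotation into the internal feature table."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = dict(
                item.split("=", 1) for item in parts[8].split(";") if "=" in item
            )
            rows.append(
                {
                    "chrom": parts[0],
                    "kind": parts[2],
                    "start": int(parts[3]),
                    "end": int(parts[4]),
                    "strand": parts[6],
                    "gene": attrs.get("ID"),
                    **{k: attrs[k] for k in ("family", "superfamily", "te_class")
                       if k in attrs},
                }
            )
    return pd.DataFrame(rows)
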