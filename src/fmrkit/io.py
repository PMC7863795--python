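"""File formats: dosage TSV (PLINK-.raw dialect), VCF, phenotype/covariate
TSV, SummaryStats TSV, GRS TSV, and the flat key-value truth ledger.

All writers/readers round-trip on supported fields; malformed input raises
:class:`fmrkit.errors.ParseError` naming the column and line.
"""

from __future__ import annotations

import math
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .assoc import SUMMARY_COLUMNS, validate_summary_stats
from .errors import ParseError
from .simulate import SimConfig, SnpSpec, TruthRecord

__all__ = [
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_vcf",
    "read_vcf",
    "write_phenotypes_tsv",
    "read_phenotypes_tsv",
    "write_summary_stats",
    "read_summary_stats",
    "write_truth",
    "read_truth",
]


# ---------------------------------------------------------------------------
# dosage TSV (PLINK .raw dialect: FID, IID, then one counted-allele column/SNP)
# ---------------------------------------------------------------------------


def write_dosage_tsv(path, dosages, snp_ids, counted_alleles=None, iids=None) -> None:
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if counted_alleles is None:
        counted_alleles = ["A"] * m
    if iids is None:
        iids = [f"id{i:07d}" for i in range(n)]
    cols = [f"{s}_{a}" for s, a in zip(snp_ids, counted_alleles)]
    with open(path, "w") as fh:
        fh.write("FID\tIID\t" + "\t".join(cols) + "\n")
        for i in range(n):
            vals = [
                "NA" if math.isnan(v) else str(int(v)) if v == int(v) else repr(v)
                for v in dosages[i]
            ]
            fh.write(f"{iids[i]}\t{iids[i]}\t" + "\t".join(vals) + "\n")


def read_dosage_tsv(path) -> tuple[np.ndarray, list[str], list[str], list[str]]:
    """Returns (dosages with NaN missing, snp_ids, counted_alleles, iids)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["FID", "IID"]:
            raise ParseError(f"{path}: header must start with FID\tIID")
        snp_cols = header[2:]
        snp_ids, alleles = [], []
        for c in snp_cols:
            sid, _, allele = c.rpartition("_")
            if not sid:
                raise ParseError(f"{path}: SNP column {c!r} lacks a _ALLELE suffix")
            snp_ids.append(sid)
            alleles.append(allele)
        rows, iids = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(f"{path}: line {lineno}: expected {len(header)} fields")
            iids.append(parts[1])
            vals = []
            for c, v in zip(snp_cols, parts[2:]):
                if v == "NA":
                    vals.append(np.nan)
                else:
                    try:
                        vals.append(float(v))
                    except ValueError:
                        raise ParseError(
                            f"{path}: line {lineno}: non-numeric dosage in column {c!r}: {v!r}"
                        ) from None
            rows.append(vals)
    return np.array(rows, dtype=float), snp_ids, alleles, iids


# ---------------------------------------------------------------------------
# VCF (v4.2, GT field only; ALT is the counted/effect allele)
# ---------------------------------------------------------------------------

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(path, dosages, snp_ids, ref_alleles=None, alt_alleles=None, iids=None) -> None:
    """Dosages are ALT-allele counts; NaN becomes './.'."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if ref_alleles is None:
        ref_alleles = ["G"] * m
    if alt_alleles is None:
        alt_alleles = ["A"] * m
    if iids is None:
        iids = [f"id{i:07d}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(iids) + "\n")
        for j in range(m):
            gts = [
                "./." if math.isnan(v) else _GT[int(round(v))] for v in dosages[:, j]
            ]
            fh.write(
                f"1\t{j + 1}\t{snp_ids[j]}\t{ref_alleles[j]}\t{alt_alleles[j]}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_vcf(path) -> tuple[np.ndarray, list[str], list[str], list[str], list[str]]:
    """Read GT-based ALT dosages via cyvcf2.

    Returns (dosages n x m with NaN for './.', snp_ids, ref, alt, iids).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    iids = list(vcf.samples)
    cols, ids, refs, alts = [], [], [], []
    for variant in vcf:
        ids.append(variant.ID)
        refs.append(variant.REF)
        alts.append(variant.ALT[0] if variant.ALT else ".")
        col = np.empty(len(iids))
        for i, g in enumerate(variant.genotypes):
            a = [x for x in g[:-1] if x >= 0]
            col[i] = float(sum(a)) if len(a) == len(g) - 1 else np.nan
        cols.append(col)
    vcf.close()
    return np.column_stack(cols) if cols else np.empty((len(iids), 0)), ids, refs, alts, iids


# ---------------------------------------------------------------------------
# phenotype / covariate / outcome TSV
# ---------------------------------------------------------------------------


def write_phenotypes_tsv(path, frame: pd.DataFrame) -> None:
    # %.17g round-trips doubles exactly
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_phenotypes_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "iid" not in df.columns:
        raise ParseError(f"{path}: phenotype table missing 'iid' column")
    return df


# ---------------------------------------------------------------------------
# summary statistics TSV
# ---------------------------------------------------------------------------


def write_summary_stats(path, stats_df: pd.DataFrame) -> None:
    cols = [c for c in SUMMARY_COLUMNS if c in stats_df.columns]
    missing = [c for c in SUMMARY_COLUMNS if c not in stats_df.columns]
    if missing:
        raise ParseError(f"summary stats to write missing columns: {missing}")
    extra = [c for c in stats_df.columns if c not in cols]
    stats_df[cols + extra].to_csv(path, sep="\t", index=False)


def read_summary_stats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: summary stats missing column(s): {missing}")
    out = df.copy()
    for col in ["eaf", "beta", "se", "pval", "n"]:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
            raise ParseError(
                f"{path}: line {line}: non-numeric value in column {col!r}: "
                f"{df[col][bad].iloc[0]!r}"
            )
        out[col] = converted
    out["n"] = out["n"].astype(int)
    validate_summary_stats(out)
    return out


# ---------------------------------------------------------------------------
# truth ledger (flat key=value text)
# ---------------------------------------------------------------------------


def _fmt(v) -> str:
    return repr(v) if isinstance(v, float) else str(v)


def write_truth(path, truth: TruthRecord) -> None:
    cfg = truth.config
    lines = []
    scalar_fields = {
        k: v
        for k, v in asdict(cfg).items()
        if k not in ("snp_spec", "covariate_effects", "ld_blocks")
    }
    for k, v in scalar_fields.items():
        lines.append(f"config.{k}={_fmt(v)}")
    for name, eff in cfg.covariate_effects.items():
        lines.append(
            f"config.covariate_effects.{name}={_fmt(eff[0])},{_fmt(eff[1])},{_fmt(eff[2])}"
        )
    for blk in cfg.ld_blocks:
        lines.append(f"config.ld_block={blk[0]},{blk[1]},{_fmt(blk[2])}")
    for s in cfg.snp_spec:
        lines.append(
            f"snp.{s.id}={_fmt(s.maf)},{_fmt(s.beta_glu)},{_fmt(s.beta_tg)},"
            f"{_fmt(s.beta_direct)},{s.effect_allele},{s.other_allele}"
        )
    for sid, af in truth.realized_eaf.items():
        lines.append(f"realized_eaf.{sid}={_fmt(af)}")
    lines.append(f"realized_sd_glu={_fmt(truth.realized_sd_glu)}")
    lines.append(f"realized_sd_tg={_fmt(truth.realized_sd_tg)}")
    lines.append(f"baseline_logodds={_fmt(truth.baseline_logodds)}")
    lines.append("pleiotropic_snps=" + ",".join(truth.pleiotropic_snps))
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_scalar(v: str):
    if v == "None":
        return None
    if v in ("True", "False"):
        return v == "True"
    try:
        return int(v)
    except ValueError:
        pass
    try:
        return float(v)
    except ValueError:
        return v


def read_truth(path) -> TruthRecord:
    cfg_kwargs: dict = {}
    cov_effects: dict = {}
    ld_blocks: list = []
    snps: list[SnpSpec] = []
    realized_eaf: dict[str, float] = {}
    extras: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if "=" not in line:
            raise ParseError(f"{path}: line {lineno}: expected key=value")
        key, _, val = line.partition("=")
        if key.startswith("config.covariate_effects."):
            name = key.rsplit(".", 1)[1]
            a, b, c = val.split(",")
            cov_effects[name] = (float(a), float(b), float(c))
        elif key == "config.ld_block":
            a, b, r = val.split(",")
            ld_blocks.append((int(a), int(b), float(r)))
        elif key.startswith("config."):
            cfg_kwargs[key[len("config."):]] = _parse_scalar(val)
        elif key.startswith("snp."):
            sid = key[len("snp."):]
            maf, bg, bt, bd, ea, oa = val.split(",")
            snps.append(
                SnpSpec(sid, float(maf), float(bg), float(bt), float(bd), ea, oa)
            )
        elif key.startswith("realized_eaf."):
            realized_eaf[key[len("realized_eaf."):]] = float(val)
        else:
            extras[key] = val
    cfg = SimConfig(
        snp_spec=snps,
        covariate_effects=cov_effects,
        ld_blocks=tuple(ld_blocks),
        **cfg_kwargs,
    )
    pleio = tuple(s for s in extras.get("pleiotropic_snps", "").split(",") if s)
    return TruthRecord(
        config=cfg,
        realized_eaf=realized_eaf,
        realized_sd_glu=float(extras["realized_sd_glu"]),
        realized_sd_tg=float(extras["realized_sd_tg"]),
        baseline_logodds=float(extras["baseline_logodds"]),
        pleiotropic_snps=pleio,
    )
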