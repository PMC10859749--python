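"""File formats: genotype/phenotype/panel CSV, VCF reading, report TSVs.

The canonical interchange for genotypes is a CSV with one row per sample,
one column per rsID and values {0, 1, 2, NA} counting the stated minor
allele.  VCF is supported read-only (GT fields converted to alternate-allele
dosage, then re-oriented so the counted allele is the minor one by observed
frequency); a minimal VCF writer exists for round-trip testing.

Report writers have two precision modes: "report" (2 decimal places, the
presentation convention of published association tables) and "machine"
(full precision).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._validation import ValidationError

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_panel",
    "write_panel",
    "read_phenotypes",
    "write_phenotypes",
    "read_vcf",
    "write_vcf",
    "write_table",
]

_PANEL_REQUIRED = ("rsid", "minor_allele", "maf_combined")


def write_genotypes(G: pd.DataFrame, path) -> None:
    G.to_csv(path, index_label="sample_id", na_rep="NA")


def read_genotypes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="sample_id", na_values=["NA"])
    if df.columns.duplicated().any():
        raise ValidationError("duplicate rsID columns in genotype CSV")
    for col in df.columns:
        vals = df[col].to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
        if bad.any():
            row = df.index[int(np.argmax(bad))]
            raise ValidationError(
                f"genotype value outside {{0,1,2,NA}} at sample {row!r}, variant {col!r}"
            )
    return df.astype(float)


def read_genotypes(path, format: str = "csv", panel: pd.DataFrame | None = None):
    """Load a genotype matrix; ``format`` is "csv" or "vcf".

    CSV returns just the matrix; VCF returns ``(matrix, panel_fragment)``
    with observed minor-allele metadata.
    """
    if format == "csv":
        return read_genotypes_csv(path)
    if format == "vcf":
        return read_vcf(path)
    raise ValidationError(f"unknown genotype format {format!r}")


def read_vcf(path):
    """Read GT fields from a (plain or bgzipped) VCF into minor dosages.

    Multi-allelic records are skipped with a warning column entry.  Returns
    ``(G, panel_fragment)`` where the fragment holds rsid, chrom_pos,
    ref/alt, the observed minor allele and its frequency.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dosages = {}
    meta = []
    for var in vcf:
        if len(var.ALT) != 1:
            continue  # multi-allelic: skipped
        rsid = var.ID or f"{var.CHROM}:{var.POS}"
        gts = var.genotypes  # [allele0, allele1, phased]
        d = np.array(
            [np.nan if g[0] < 0 or g[1] < 0 else float((g[0] > 0) + (g[1] > 0)) for g in gts]
        )
        obs = d[~np.isnan(d)]
        alt_freq = obs.mean() / 2.0 if obs.size else float("nan")
        minor = var.ALT[0]
        if alt_freq > 0.5:  # re-orient to the minor allele
            d = 2.0 - d
            minor = var.REF
            alt_freq = 1.0 - alt_freq
        dosages[rsid] = d
        meta.append(
            {
                "rsid": rsid,
                "chrom_pos": f"{var.CHROM}:{var.POS}",
                "ref": var.REF,
                "alt": var.ALT[0],
                "minor_allele": minor,
                "maf_combined": alt_freq,
            }
        )
    idx = pd.Index(samples, name="sample_id")
    return pd.DataFrame(dosages, index=idx), pd.DataFrame(meta)


def write_vcf(G: pd.DataFrame, panel: pd.DataFrame, path) -> None:
    """Minimal single-sample-block VCF with GT fields (round-trip support).

    Dosages count the panel's minor allele; GT is emitted on REF/ALT with the
    ALT taken from the panel, inverting the coding when the minor allele is
    the REF.
    """
    pan = panel.set_index("rsid")
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(G.index),
    ]
    gt_for = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for rsid in G.columns:
        row = pan.loc[rsid]
        chrom, pos = str(row["chrom_pos"]).replace(" ", "").split(":")
        minor_is_alt = row["minor_allele"] == row["alt"]
        gts = []
        for d in G[rsid]:
            if np.isnan(d):
                gts.append("./.")
            else:
                gts.append(gt_for[d if minor_is_alt else 2.0 - d])
        lines.append(
            "\t".join([chrom, pos, rsid, row["ref"], row["alt"], ".", "PASS", ".", "GT"] + gts)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_panel(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _PANEL_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"panel file missing columns: {missing}")
    if df["rsid"].duplicated().any():
        raise ValidationError("duplicate rsIDs in panel")
    for col in ("maf_combined", "maf_rural", "maf_urban"):
        if col in df.columns and not df[col].between(0, 0.5).all():
            raise ValidationError(f"{col} outside [0, 0.5]")
    return df


def write_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")


def write_phenotypes(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index_label="sample_id")


def write_table(df: pd.DataFrame, path, precision: str = "machine") -> None:
    """TSV writer with deterministic column order and fixed formatting."""
    if precision == "report":
        out = df.copy()
        for col in out.columns:
            if pd.api.types.is_float_dtype(out[col]):
                if col in ("p", "hwe_p_combined", "hwe_p_rural", "hwe_p_urban"):
                    out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.3f}")
                else:
                    out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
        out.to_csv(path, sep="\t", index=False)
    elif precision == "machine":
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    else:
        raise ValidationError(f"unknown precision mode {precision!r}")
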