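"""Readers and writers for the pipeline's plain-text formats.

Manifest and sample sheet are CSV; β, detection-p, intensity, truth,
calls and burden tables are TSV.  Intensity tables carry three columns
per sample: ``<sample>.Methylated``, ``<sample>.Unmethylated`` and
``<sample>.Detection_Pval``.  Call coordinates export to BED with
0-based half-open intervals.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

MANIFEST_COLUMNS = ["IlmnID", "CHR", "MAPINFO", "UCSC_RefGene_Name",
                    "UCSC_RefGene_Group", "Relation_to_UCSC_CpG_Island",
                    "Probe_SNPs", "Probe_SNPs_10"]


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, index=False, columns=MANIFEST_COLUMNS)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"CHR": str}, keep_default_na=False,
                     na_values=[])
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest lacks columns: {sorted(missing)}")
    df["MAPINFO"] = df["MAPINFO"].astype(int)
    if df["IlmnID"].duplicated().any():
        raise ValueError("duplicate probe ids in manifest")
    return df


def write_beta(beta: pd.DataFrame, path) -> None:
    beta.to_csv(path, sep="\t", index_label=beta.index.name or "IlmnID",
                float_format="%.6g")


def read_beta(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path)
    if "Sample_ID" not in sheet.columns:
        raise ValueError("sample sheet must have a Sample_ID column")
    return sheet


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_calls(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_calls(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
        fh.write("\n")


# -- intensities ------------------------------------------------------------

def intensities_from_beta(beta: pd.DataFrame, detection_p: pd.DataFrame,
                          total_intensity: float = 30_000.0
                          ) -> pd.DataFrame:
    """Construct an intensity table whose β recomputes exactly.

    With S = M + U + 100 fixed at ``total_intensity``, M = β·S and
    U = S - 100 - M, so β = M/(U + M + 100) recovers the input
    (requires β < 1 - 100/S).
    """
    S = float(total_intensity)
    M = beta * S
    U = S - 100.0 - M
    if (U.to_numpy() < 0).any():
        raise ValueError("total_intensity too small for the largest β")
    cols = {}
    for s in beta.columns:
        cols[f"{s}.Methylated"] = M[s]
        cols[f"{s}.Unmethylated"] = U[s]
        cols[f"{s}.Detection_Pval"] = detection_p[s]
    out = pd.DataFrame(cols, index=beta.index)
    out.index.name = beta.index.name or "IlmnID"
    return out


def write_intensities(intensities: pd.DataFrame, path) -> None:
    intensities.to_csv(path, sep="\t", float_format="%.6g")


def read_intensities(path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Return (methylated, unmethylated, detection_p) probe x sample frames."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    samples = sorted({c.rsplit(".", 1)[0] for c in df.columns})
    meth = pd.DataFrame({s: df[f"{s}.Methylated"] for s in samples})
    unmeth = pd.DataFrame({s: df[f"{s}.Unmethylated"] for s in samples})
    detp = pd.DataFrame({s: df[f"{s}.Detection_Pval"] for s in samples})
    return meth, unmeth, detp


# -- BED export -------------------------------------------------------------

def write_bed(calls: pd.DataFrame, path) -> None:
    """One 0-based half-open interval per called CpG.

    name = sample id, score = round(1000·|Δβ|) capped at 1000.  Calls
    need ``chromosome``/``position`` columns (from annotate_calls).
    """
    if "chromosome" not in calls or "position" not in calls:
        raise ValueError("calls must be annotated with chromosome/position")
    with open(path, "w") as fh:
        for _, row in calls.iterrows():
            chrom = str(row["chromosome"])
            if not chrom or chrom == "0":
                continue
            if not chrom.startswith("chr"):
                chrom = "chr" + chrom
            start = int(row["position"]) - 1
            score = min(1000, int(round(1000 * abs(row["delta_beta"]))))
            fh.write(f"{chrom}\t{start}\t{start + 1}\t{row['sample_id']}\t{score}\n")
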