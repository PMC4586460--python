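"""β computation from signal intensities and probe-exclusion filtering.

The methylation level of a CpG is summarised as
``β = M / (U + M + 100)`` where M and U are the methylated and
unmethylated allele intensities; the +100 offset regularises
low-intensity probes, so β lies in [0, 1).

Probe exclusion removes, in order: sex-chromosome probes, the rs-named
genotyping control probes (which assay highly polymorphic SNPs rather
than methylation), probes whose detection p-value exceeds the threshold
in one or more samples, and probes with a missing β in one or more
samples.  Each removed probe is attributed to the first rule it
triggers, so the report's counts always reconcile with the input size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FILTER_RULES = ("sex_chromosome", "rs_control", "detection_p", "missing_beta")


@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    removed: dict[str, int] = field(default_factory=dict)
    detection_p_threshold: float = 0.01

    def __post_init__(self) -> None:
        total = self.n_retained + sum(self.removed.values())
        if total != self.n_input:
            raise ValueError("filter report does not reconcile: "
                             f"{self.n_retained} retained + removed "
                             f"{self.removed} != {self.n_input} input")

    def to_dict(self) -> dict:
        return {"n_input": self.n_input, "n_retained": self.n_retained,
                "removed": dict(self.removed),
                "detection_p_threshold": self.detection_p_threshold}


def compute_beta(M, U):
    """β = M / (U + M + 100) for non-negative intensities (vectorised)."""
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if np.any(M < 0) or np.any(U < 0):
        raise ValueError("intensities must be non-negative")
    out = M / (U + M + 100.0)
    return out if out.ndim else float(out)


def beta_from_intensities(meth: pd.DataFrame, unmeth: pd.DataFrame) -> pd.DataFrame:
    """Probe x sample β matrix from aligned methylated/unmethylated tables."""
    if not meth.index.equals(unmeth.index) or not meth.columns.equals(unmeth.columns):
        raise ValueError("methylated and unmethylated tables must be aligned")
    beta = pd.DataFrame(compute_beta(meth.to_numpy(), unmeth.to_numpy()),
                        index=meth.index, columns=meth.columns)
    beta.index.name = meth.index.name or "IlmnID"
    return beta


def filter_probes(beta: pd.DataFrame,
                  manifest: pd.DataFrame,
                  detection_p: pd.DataFrame | None = None,
                  detection_p_threshold: float = 0.01,
                  ) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the probe-exclusion rules; return the retained β and a report.

    ``beta`` is probes x samples with the manifest's ``IlmnID`` as index.
    ``detection_p`` (same shape) is optional; without it the detection
    rule removes nothing.  A probe present in ``beta`` but absent from
    the manifest is an error.
    """
    idx = beta.index
    mani = manifest.set_index("IlmnID")
    unknown = idx.difference(mani.index)
    if len(unknown):
        raise ValueError(f"probes absent from manifest: {list(unknown[:5])!r}...")
    mani = mani.loc[idx]

    chrom = mani["CHR"].fillna("").astype(str)
    sex = chrom.isin(["X", "Y", "chrX", "chrY"]).to_numpy()
    rs = np.asarray(idx.astype(str).str.startswith("rs"))
    if detection_p is not None:
        dp = detection_p.reindex(index=idx, columns=beta.columns)
        det_fail = (dp.to_numpy() > detection_p_threshold).any(axis=1) \
            | np.isnan(dp.to_numpy()).any(axis=1)
    else:
        det_fail = np.zeros(len(idx), dtype=bool)
    missing = np.isnan(beta.to_numpy()).any(axis=1)

    removed: dict[str, int] = {}
    dropped = np.zeros(len(idx), dtype=bool)
    for rule, mask in zip(FILTER_RULES, (sex, rs, det_fail, missing)):
        new = mask & ~dropped
        removed[rule] = int(new.sum())
        dropped |= mask
    kept = beta.loc[~dropped]
    report = FilterReport(n_input=len(idx), n_retained=len(kept),
                          removed=removed,
                          detection_p_threshold=detection_p_threshold)
    return kept, report
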