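"""Genomic annotation of outlier calls and gene-set utilities.

Calls are annotated with the probe's CpG-island relation, the lead-off
gene symbol and feature group (first entry of the manifest's
semicolon-joined lists), a pTSS flag (feature in TSS1500, TSS200,
5'UTR or 1stExon — the promoter-proximal groups), and a
clustered/isolated status: calls at two or more probes that are
consecutive rows of the retained manifest on the same chromosome form a
cluster.  Gene subgroup selection and a generic hypergeometric
enrichment against user-supplied gene sets (GMT format) mirror the
downstream functional analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .group_tests import bh_adjust
from .outliers import ScanResult
from .simulate import PTSS_FEATURES, chromosome_sort_key

GENIC_FEATURES = ("TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR")

_RELATION_GROUP = {
    "Island": "island", "N_Shore": "shore", "S_Shore": "shore",
    "N_Shelf": "shelf", "S_Shelf": "shelf", "": "open_sea",
}


def _check_sorted(manifest: pd.DataFrame) -> None:
    key = chromosome_sort_key(manifest["CHR"].fillna("").astype(str)).to_numpy()
    pos = manifest["MAPINFO"].to_numpy()
    order = np.lexsort((pos, key))
    if not np.array_equal(order, np.arange(len(manifest))):
        raise ValueError("manifest must be sorted by (chromosome, position)")


def annotate_calls(result: ScanResult, manifest: pd.DataFrame) -> pd.DataFrame:
    """Attach CGI relation, lead gene/feature and pTSS flag to each call."""
    _check_sorted(manifest)
    mani = manifest.set_index("IlmnID")
    missing = set(result.calls["probe_id"]) - set(mani.index)
    if missing:
        raise ValueError(f"called probes absent from manifest: {sorted(missing)[:5]!r}")
    sub = mani.reindex(result.calls["probe_id"])

    rel = sub["Relation_to_UCSC_CpG_Island"].fillna("").astype(str).to_numpy()
    genes = sub["UCSC_RefGene_Name"].fillna("").astype(str)
    feats = sub["UCSC_RefGene_Group"].fillna("").astype(str)
    lead_gene = genes.str.split(";").str[0].to_numpy()
    lead_feat = feats.str.split(";").str[0].to_numpy()

    out = result.calls.copy()
    out["chromosome"] = sub["CHR"].fillna("").astype(str).to_numpy()
    out["position"] = sub["MAPINFO"].to_numpy()
    out["cgi_relation"] = rel
    out["cgi_group"] = [_RELATION_GROUP.get(r, "open_sea") for r in rel]
    out["lead_gene"] = np.where(lead_gene == "", "intergenic", lead_gene)
    out["lead_feature"] = np.where(lead_feat == "", "intergenic", lead_feat)
    out["ptss"] = np.isin(lead_feat, PTSS_FEATURES)
    out["genic"] = np.isin(lead_feat, GENIC_FEATURES)
    return out


def cluster_calls(calls: pd.DataFrame, manifest: pd.DataFrame,
                  same_sample: bool = True,
                  max_gap_bp: int | None = None) -> pd.DataFrame:
    """Assign cluster ids; clusters are runs of calls at adjacent probes.

    Adjacency means consecutive rows of the (retained) manifest on the
    same chromosome, optionally within ``max_gap_bp`` base pairs.
    Clusters never mix directions; with ``same_sample`` (default) they
    never mix samples either.  Adds ``cluster_id`` (NaN for isolated
    calls), ``cluster_size`` and boolean ``clustered``.
    """
    _check_sorted(manifest)
    row_of = pd.Series(np.arange(len(manifest)), index=manifest["IlmnID"])
    chrom_of = pd.Series(manifest["CHR"].fillna("").astype(str).to_numpy(),
                         index=manifest["IlmnID"])
    pos_of = pd.Series(manifest["MAPINFO"].to_numpy(), index=manifest["IlmnID"])

    out = calls.copy()
    out["_row"] = row_of.reindex(out["probe_id"]).to_numpy()
    if np.isnan(out["_row"]).any():
        raise ValueError("calls reference probes absent from manifest")
    out["_chrom"] = chrom_of.reindex(out["probe_id"]).to_numpy()
    out["_pos"] = pos_of.reindex(out["probe_id"]).to_numpy()
    out = out.sort_values("_row", kind="stable")

    rows = out["_row"].to_numpy()
    chroms = out["_chrom"].to_numpy()
    pos = out["_pos"].to_numpy()
    dirs = out["direction"].to_numpy()
    samples = out["sample_id"].to_numpy()

    cluster = np.zeros(len(out), dtype=int)
    current = 0
    for i in range(len(out)):
        if i == 0:
            current = 1
        else:
            adjacent = (rows[i] == rows[i - 1] + 1
                        and chroms[i] == chroms[i - 1]
                        and dirs[i] == dirs[i - 1]
                        and (not same_sample or samples[i] == samples[i - 1]))
            if adjacent and max_gap_bp is not None:
                adjacent = (pos[i] - pos[i - 1]) <= max_gap_bp
            if not adjacent:
                current += 1
        cluster[i] = current
    out["cluster_id"] = cluster
    sizes = out.groupby("cluster_id")["probe_id"].transform("size")
    out["cluster_size"] = sizes.to_numpy()
    out["clustered"] = out["cluster_size"] >= 2
    out.loc[~out["clustered"], "cluster_id"] = np.nan
    out = out.drop(columns=["_row", "_chrom", "_pos"])
    return out.sort_index()


def feature_summary(calls: pd.DataFrame) -> dict[str, dict]:
    """Fig-2-style per-direction composition of annotated calls.

    Fractions of calls by CGI-relation group and by lead feature group,
    the genic fraction, the number of distinct host genes, and (when
    clustering has been run) the clustered fraction.
    """
    out: dict[str, dict] = {}
    for direction in ("hyper", "hypo"):
        sub = calls[calls["direction"] == direction]
        n = len(sub)
        if n == 0:
            continue
        entry: dict = {"n": n}
        entry["cgi"] = (sub["cgi_group"].value_counts(normalize=True)
                        .to_dict())
        entry["features"] = (sub["lead_feature"].value_counts(normalize=True)
                             .to_dict())
        entry["genic_fraction"] = float(sub["genic"].mean())
        entry["ptss_fraction"] = float(sub["ptss"].mean())
        genes = sub.loc[sub["genic"], "lead_gene"]
        entry["n_host_genes"] = int(genes.nunique())
        if "clustered" in sub:
            entry["clustered_fraction"] = float(sub["clustered"].mean())
        out[direction] = entry
    return out


def select_gene_subgroups(calls: pd.DataFrame,
                          delta_threshold: float = 0.2) -> dict[str, set[str]]:
    """Host-gene subgroups per direction, via lead symbols.

    For each direction: all host genes, genes hosting highly deviated
    calls (|Δβ| strictly greater than ``delta_threshold``), genes with
    calls in the pTSS, genes with clustered calls, and the intersection
    subgroup (highly deviated AND clustered AND pTSS on a single call).
    """
    if "clustered" not in calls:
        raise ValueError("calls must be clustered first (cluster_calls)")
    groups: dict[str, set[str]] = {}
    genic = calls[calls["genic"]]
    for direction in ("hyper", "hypo"):
        sub = genic[genic["direction"] == direction]
        high = sub["delta_beta"].abs() > delta_threshold
        groups[f"{direction}_all"] = set(sub["lead_gene"])
        groups[f"{direction}_high_delta"] = set(sub.loc[high, "lead_gene"])
        groups[f"{direction}_ptss"] = set(sub.loc[sub["ptss"], "lead_gene"])
        groups[f"{direction}_clustered"] = set(sub.loc[sub["clustered"], "lead_gene"])
        groups[f"{direction}_high_clustered_ptss"] = set(
            sub.loc[high & sub["clustered"] & sub["ptss"], "lead_gene"])
    return groups


def enrichment(genes: set[str], universe: set[str],
               annotation_sets: dict[str, set[str]]) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of ``genes`` against each term.

    Fold enrichment = (k/n) / (K/N) with k the overlap, n the query
    size, K the term size within the universe and N the universe size.
    BH adjustment across terms.
    """
    genes = set(genes)
    universe = set(universe)
    if not genes or not universe or not annotation_sets:
        raise ValueError("gene set, universe and annotation sets must be non-empty")
    outside = genes - universe
    if outside:
        raise ValueError(f"query genes outside the universe: {sorted(outside)[:5]!r}")
    N, n = len(universe), len(genes)
    rows = []
    for term, members in annotation_sets.items():
        members = set(members) & universe
        K = len(members)
        k = len(genes & members)
        fold = (k / n) / (K / N) if K else np.nan
        p = hypergeom.sf(k - 1, N, K, n) if K else 1.0
        rows.append({"term": term, "overlap": k, "term_size": K,
                     "query_size": n, "universe_size": N,
                     "fold_enrichment": fold, "p": float(p)})
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    return table.sort_values("p", kind="stable").reset_index(drop=True)


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets from a GMT file (term, description, genes...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3 and parts[0]:
                sets[parts[0]] = {g for g in parts[2:] if g}
    return sets
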