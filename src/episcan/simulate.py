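"""Synthetic Illumina-450K-like cohort generator.

Produces a manifest-like probe annotation table, a sample sheet, a β
matrix with batch effects and injected individual-specific epimutations,
a per-cell detection p-value table, and a ground-truth table of every
injection for recovery scoring.

Statistical structure emulated
------------------------------
* bimodal marginal β: CpG-island promoter probes are drawn from a
  low-methylation component (β ≈ 0.02-0.07), open-sea probes from a
  high component (β ≈ 0.87-0.97), with a small intermediate fraction;
* per-probe biological variance plus measurement noise applied on the
  logit scale (heteroscedastic near 0/1 on the β scale, as on arrays);
* an additive location shift and multiplicative scale per array batch,
  also on the logit scale (the model class ComBat removes);
* trimodal β (≈0/0.5/1 across genotypes) at a fraction of SNP-flagged
  probes, mimicking sequence-dependent allele-specific methylation;
* hypermethylation epimutations injected as runs of two or more
  adjacent low-baseline CGI-promoter probes, hypomethylation as
  isolated high-baseline open-sea probes, with signed Δβ magnitudes
  drawn from the configured effect-size distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .config import CATEGORIES, DEFAULT_GWG_KG, SimulationConfig

PTSS_FEATURES = ("TSS1500", "TSS200", "5'UTR", "1stExon")
CGI_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "")

_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "": 99}


def chromosome_sort_key(chrom: pd.Series) -> pd.Series:
    """Numeric ordering key: 1..22, X, Y, then unplaced/control probes."""
    return chrom.map(lambda c: _CHROM_ORDER.get(str(c), 98))


@dataclass
class SimulatedCohort:
    """Artifacts of one synthetic cohort draw."""

    beta: pd.DataFrame          # probes x samples, index = IlmnID
    detection_p: pd.DataFrame   # same shape as beta
    sample_sheet: pd.DataFrame
    truth: pd.DataFrame         # one row per injected (probe, sample)


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def generate_manifest(config: SimulationConfig) -> pd.DataFrame:
    """Generate a HumanMethylation450-manifest-like probe annotation table.

    Columns follow the array manifest conventions: ``IlmnID``, ``CHR``,
    ``MAPINFO`` (1-based position), semicolon-joined ``UCSC_RefGene_Name``
    and ``UCSC_RefGene_Group``, ``Relation_to_UCSC_CpG_Island`` (empty =
    open sea), and the two SNP-flag columns ``Probe_SNPs`` /
    ``Probe_SNPs_10``.  Probes are sorted by (chromosome, position);
    rs-named genotyping control probes sort last with no coordinates.
    """
    config.validate()
    layout = config.layout()
    if sum(n for _, n in layout) <= 0:
        raise ValueError("chromosome layout contains zero probes")
    rng = np.random.default_rng([config.seed, 0])

    rows_chrom: list[str] = []
    rows_pos: list[int] = []
    rows_gene: list[str] = []
    rows_feat: list[str] = []
    rows_rel: list[str] = []
    gene_counter = 0
    body_counter = 0

    for chrom, n_c in layout:
        if n_c <= 0:
            continue
        n_prom = int(round(config.fraction_cgi_promoter * n_c))
        # promoter block lengths (runs of adjacent CGI-promoter probes)
        block_lengths: list[int] = []
        remaining = n_prom
        while remaining >= 2:
            size = int(rng.integers(4, 13))
            if remaining - size == 1:
                size += 1
            size = min(size, remaining)
            block_lengths.append(size)
            remaining -= size
        n_prom = sum(block_lengths)
        n_open = n_c - n_prom

        # interleave block units among open-sea probes
        units = np.concatenate([np.zeros(n_open, dtype=int),
                                np.arange(1, len(block_lengths) + 1)])
        rng.shuffle(units)

        pos = int(rng.integers(10_000, 50_000))
        for unit in units:
            pos += int(rng.integers(2_000, 20_000))
            if unit == 0:  # single probe outside CGIs
                rows_chrom.append(chrom)
                rows_pos.append(pos)
                rows_rel.append("")
                r = rng.random()
                if r < 0.55:
                    body_counter += 1
                    rows_gene.append(f"BGENE{body_counter:05d}")
                    rows_feat.append("Body")
                elif r < 0.60:
                    body_counter += 1
                    rows_gene.append(f"BGENE{body_counter:05d}")
                    rows_feat.append("3'UTR")
                else:
                    rows_gene.append("")
                    rows_feat.append("")
            else:
                size = block_lengths[unit - 1]
                gene_counter += 1
                gene = f"GENE{gene_counter:05d}"
                two_genes = rng.random() < 0.10
                shelf_edges = rng.random() < 0.10
                feats = rng.choice(PTSS_FEATURES, size=size,
                                   p=(0.3, 0.3, 0.2, 0.2))
                for j in range(size):
                    rows_chrom.append(chrom)
                    rows_pos.append(pos)
                    pos += int(rng.integers(30, 200))
                    if size >= 4 and j == 0:
                        rows_rel.append("N_Shelf" if shelf_edges else "N_Shore")
                    elif size >= 4 and j == size - 1:
                        rows_rel.append("S_Shelf" if shelf_edges else "S_Shore")
                    else:
                        rows_rel.append("Island")
                    if two_genes:
                        rows_gene.append(f"{gene};{gene}B")
                        rows_feat.append(f"{feats[j]};Body")
                    else:
                        rows_gene.append(gene)
                        rows_feat.append(str(feats[j]))

    # sex-chromosome probes
    n_sex = config.n_sex_chrom_probes
    n_y = n_sex // 10
    for chrom, n_c in (("X", n_sex - n_y), ("Y", n_y)):
        positions = np.sort(rng.integers(10_000, 150_000_000, size=n_c))
        for p in positions:
            rows_chrom.append(chrom)
            rows_pos.append(int(p))
            rows_rel.append(str(rng.choice(CGI_RELATIONS)))
            rows_gene.append("")
            rows_feat.append("")

    n_auto_sex = len(rows_chrom)
    ids = [f"cg{i + 1:08d}" for i in range(n_auto_sex)]

    # rs-named genotyping control probes (assay SNPs, not methylation)
    for i in range(config.n_rs_control_probes):
        ids.append(f"rs{1000000 + i}")
        rows_chrom.append("")
        rows_pos.append(0)
        rows_rel.append("")
        rows_gene.append("")
        rows_feat.append("")

    manifest = pd.DataFrame({
        "IlmnID": ids,
        "CHR": rows_chrom,
        "MAPINFO": rows_pos,
        "UCSC_RefGene_Name": rows_gene,
        "UCSC_RefGene_Group": rows_feat,
        "Relation_to_UCSC_CpG_Island": rows_rel,
        "Probe_SNPs": "",
        "Probe_SNPs_10": "",
    })

    # SNP flags on measurement probes only
    is_cg = manifest["IlmnID"].str.startswith("cg").to_numpy()
    flagged = (rng.random(len(manifest)) < config.fraction_snp_flagged) & is_cg
    which_col = rng.random(len(manifest)) < 0.5
    snp_ids = np.array([f"rs{int(x)}" for x in rng.integers(10**4, 10**8,
                                                            size=len(manifest))])
    manifest.loc[flagged & which_col, "Probe_SNPs"] = snp_ids[flagged & which_col]
    manifest.loc[flagged & ~which_col, "Probe_SNPs_10"] = snp_ids[flagged & ~which_col]

    manifest = manifest.sort_values(
        ["MAPINFO"]).sort_values(
        "CHR", key=chromosome_sort_key, kind="stable").reset_index(drop=True)
    if manifest["IlmnID"].duplicated().any():
        raise ValueError("duplicate probe ids in generated manifest")
    return manifest


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def probe_classes(manifest: pd.DataFrame) -> pd.DataFrame:
    """Derive per-probe classes used by the generator and the filters."""
    ilmn = manifest["IlmnID"].astype(str)
    chrom = manifest["CHR"].fillna("").astype(str)
    rel = manifest["Relation_to_UCSC_CpG_Island"].fillna("").astype(str)
    feat = manifest["UCSC_RefGene_Group"].fillna("").astype(str)
    lead_feat = feat.str.split(";").str[0]
    snp1 = manifest["Probe_SNPs"].fillna("").astype(str) != ""
    snp2 = manifest["Probe_SNPs_10"].fillna("").astype(str) != ""
    return pd.DataFrame({
        "is_rs_control": ilmn.str.startswith("rs"),
        "is_sex": chrom.isin(["X", "Y", "chrX", "chrY"]),
        "snp_flagged": snp1 | snp2,
        "cgi_promoter": (rel != "") & lead_feat.isin(PTSS_FEATURES),
        "open_sea": (rel == "") & ~ilmn.str.startswith("rs")
                    & ~chrom.isin(["X", "Y", "chrX", "chrY"]),
    }, index=manifest.index)


def _truncated_normal(rng, mean, sd, lower, upper, size):
    if sd == 0:
        val = np.full(size, mean, dtype=float)
        return np.clip(val, lower, upper)
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _sample_sheet(config: SimulationConfig, rng) -> pd.DataFrame:
    rows = []
    idx = 0
    for cat in CATEGORIES:
        n = config.category_sizes[cat]
        pheno, gwg = cat.split("_", 1)
        mean, sd, lo, hi = DEFAULT_GWG_KG[cat]
        kgs = np.clip(rng.normal(mean, sd, size=n), lo, hi)
        for i in range(n):
            rows.append({
                "Sample_ID": f"{cat}_{i + 1}",
                "phenotype": pheno,
                "gwg_category": gwg,
                "category": cat,
                "gwg_kg": round(float(kgs[i]), 1),
                "batch": config.batch_labels[idx % len(config.batch_labels)],
            })
            idx += 1
    return pd.DataFrame(rows)


def _eligible_runs(eligible: np.ndarray, retained_order: np.ndarray) -> list[np.ndarray]:
    """Maximal runs of eligible probes consecutive in the retained manifest."""
    runs = []
    current: list[int] = []
    for row in retained_order:
        if eligible[row]:
            current.append(row)
        else:
            if len(current) >= 2:
                runs.append(np.asarray(current))
            current = []
    if len(current) >= 2:
        runs.append(np.asarray(current))
    return runs


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def generate_cohort(config: SimulationConfig,
                    manifest: pd.DataFrame) -> SimulatedCohort:
    """Simulate β values, detection p-values, sample sheet and injection truth.

    Raises
    ------
    ValueError
        If a category's configured burden exceeds the eligible probes
        available for injection (the error names the category).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    sheet = _sample_sheet(config, rng)
    n_samples = len(sheet)
    if n_samples < 3:
        raise ValueError("cohort must contain at least 3 samples")
    n_probes = len(manifest)
    cls = probe_classes(manifest)

    # ---- per-probe baselines -------------------------------------------
    mu = np.empty(n_probes)
    sd_logit = np.empty(n_probes)
    promoter = cls["cgi_promoter"].to_numpy()
    opensea = cls["open_sea"].to_numpy()
    sex = cls["is_sex"].to_numpy()
    rs_ctrl = cls["is_rs_control"].to_numpy()
    flagged = cls["snp_flagged"].to_numpy()
    other = ~(promoter | opensea | sex | rs_ctrl)

    lo, hi = config.promoter_beta_low
    mu[promoter] = rng.uniform(lo, hi, promoter.sum())
    lo, hi = config.opensea_beta_high
    mu[opensea] = rng.uniform(lo, hi, opensea.sum())
    mu[sex] = rng.uniform(0.2, 0.8, sex.sum())
    mu[other] = rng.uniform(0.2, 0.8, other.sum())
    mu[rs_ctrl] = 0.5
    # a small intermediate component keeps the mixture from being a caricature
    inter = (rng.random(n_probes) < config.fraction_intermediate) & (promoter | opensea)
    mu[inter] = rng.uniform(0.2, 0.6, inter.sum())

    sd_logit[:] = rng.uniform(*config.opensea_logit_sd, n_probes)
    sd_logit[promoter] = rng.uniform(*config.promoter_logit_sd, promoter.sum())

    # ---- noise + batch effects on the logit scale ----------------------
    batch_of = sheet["batch"].to_numpy()
    shift = dict(zip(config.batch_labels, config.batch_logit_shift))
    scale = dict(zip(config.batch_labels, config.batch_logit_scale))
    shifts = np.array([shift[b] for b in batch_of])
    scales = np.array([scale[b] for b in batch_of])

    z = rng.standard_normal((n_probes, n_samples))
    lgt = logit(np.clip(mu, 1e-6, 1 - 1e-6))[:, None] + shifts[None, :] \
        + scales[None, :] * sd_logit[:, None] * z
    beta = expit(lgt)

    # ---- genotype-driven trimodal probes (rs controls + ASM artifacts) -
    asm = flagged & (rng.random(n_probes) < config.asm_fraction) & ~sex & ~rs_ctrl
    genotype_rows = np.flatnonzero(asm | rs_ctrl)
    if genotype_rows.size:
        maf = np.where(rs_ctrl[genotype_rows],
                       rng.uniform(0.2, 0.5, genotype_rows.size),
                       rng.uniform(0.05, 0.3, genotype_rows.size))
        genotypes = rng.binomial(2, maf[:, None], (genotype_rows.size, n_samples))
        mu_g = np.array([0.03, 0.5, 0.97])[genotypes]
        lgt_g = logit(mu_g) + shifts[None, :] \
            + scales[None, :] * 0.1 * rng.standard_normal(mu_g.shape)
        beta[genotype_rows] = expit(lgt_g)

    # ---- detection p-values --------------------------------------------
    detection_p = rng.uniform(0.0, 0.009, (n_probes, n_samples))
    cg_auto = ~(sex | rs_ctrl)
    fail_pool = np.flatnonzero(cg_auto)
    n_fail = min(config.n_detection_fail_probes, fail_pool.size)
    fail_rows = rng.choice(fail_pool, size=n_fail, replace=False)
    fail_cols = rng.integers(0, n_samples, size=n_fail)
    detection_p[fail_rows, fail_cols] = rng.uniform(0.02, 0.5, size=n_fail)
    failed = np.zeros(n_probes, dtype=bool)
    failed[fail_rows] = True

    # ---- injection eligibility -----------------------------------------
    usable = ~(flagged | sex | rs_ctrl | failed | inter)
    hyper_ok = promoter & usable & (mu < 0.10)
    hypo_ok = opensea & usable & (mu > 0.85)

    retained = ~(sex | rs_ctrl | failed)  # rows surviving the probe filters
    retained_order = np.flatnonzero(retained)
    chrom_arr = manifest["CHR"].fillna("").astype(str).to_numpy()
    # break eligibility runs at chromosome boundaries
    hyper_runs_ok = hyper_ok.copy()
    segments: list[list[int]] = []
    cur: list[int] = []
    prev_chrom = None
    for row in retained_order:
        if hyper_runs_ok[row] and chrom_arr[row] == prev_chrom:
            cur.append(row)
        elif hyper_runs_ok[row]:
            if len(cur) >= 2:
                segments.append(cur)
            cur = [row]
        else:
            if len(cur) >= 2:
                segments.append(cur)
            cur = []
        prev_chrom = chrom_arr[row] if hyper_runs_ok[row] else None
    if len(cur) >= 2:
        segments.append(cur)

    hypo_pool = list(np.flatnonzero(hypo_ok))
    rng.shuffle(hypo_pool)

    # ---- per-sample burdens --------------------------------------------
    m_hyper, s_hyper = config.hyper_delta
    m_hypo, s_hypo = config.hypo_delta
    probe_ids = manifest["IlmnID"].to_numpy()
    records = []
    cluster_counter = 0

    for _, sample in sheet.iterrows():
        cat = sample["category"]
        lo_b, hi_b = config.burden_per_category[cat]
        burden = int(rng.integers(lo_b, hi_b + 1)) if hi_b > lo_b else lo_b
        n_hyper = int(round(config.fraction_hyper * burden))
        n_hypo = burden - n_hyper

        # hyper: runs of >= 2 adjacent eligible promoter probes; drawn run
        # lengths are capped by the longest free segment still available
        remaining = n_hyper
        while remaining >= 2:
            max_seg = max((len(s) for s in segments), default=0)
            if max_seg < 2:
                raise ValueError(
                    f"hyper burden for category {cat!r} exceeds the eligible "
                    "CGI-promoter probe runs; reduce burden_per_category or "
                    "increase n_probes/fraction_cgi_promoter")
            size = min(1 + int(rng.geometric(config.cluster_length_geom_p)),
                       config.max_cluster_length, remaining, max_seg)
            if remaining - size == 1:
                if size + 1 <= min(config.max_cluster_length, remaining, max_seg):
                    size += 1
                elif size - 1 >= 2:
                    size -= 1
            size = max(size, 2)
            remaining -= size
            candidates = [k for k, seg in enumerate(segments) if len(seg) >= size]
            k = candidates[int(rng.integers(len(candidates)))]
            seg = segments.pop(k)
            start = int(rng.integers(0, len(seg) - size + 1))
            chosen = seg[start:start + size]
            # one-probe buffer keeps independently injected runs non-adjacent
            left = seg[:max(start - 1, 0)]
            right = seg[start + size + 1:]
            if len(left) >= 2:
                segments.append(left)
            if len(right) >= 2:
                segments.append(right)
            cluster_counter += 1
            deltas = _truncated_normal(rng, m_hyper, s_hyper,
                                       config.min_abs_delta, 1.0, size)
            cols = sheet.index[sheet["Sample_ID"] == sample["Sample_ID"]][0]
            for row, d in zip(chosen, deltas):
                beta[row, cols] = min(beta[row, cols] + d, 1.0)
                records.append((sample["Sample_ID"], probe_ids[row], float(d),
                                "hyper", f"cluster{cluster_counter}"))

        # hypo: isolated open-sea probes
        if n_hypo > len(hypo_pool):
            raise ValueError(
                f"hypo burden for category {cat!r} exceeds the eligible "
                "open-sea probes; reduce burden_per_category or increase n_probes")
        cols = sheet.index[sheet["Sample_ID"] == sample["Sample_ID"]][0]
        for _ in range(n_hypo):
            row = hypo_pool.pop()
            d = float(_truncated_normal(rng, m_hypo, s_hypo,
                                        -1.0, -config.min_abs_delta, 1)[0])
            beta[row, cols] = max(beta[row, cols] + d, 0.0)
            records.append((sample["Sample_ID"], probe_ids[row], d,
                            "hypo", "isolated"))

    truth = pd.DataFrame(records, columns=["sample_id", "probe_id",
                                           "injected_delta", "direction",
                                           "cluster_id"])
    samples = sheet["Sample_ID"].tolist()
    beta_df = pd.DataFrame(beta, index=probe_ids, columns=samples)
    beta_df.index.name = "IlmnID"
    detp_df = pd.DataFrame(detection_p, index=probe_ids, columns=samples)
    detp_df.index.name = "IlmnID"
    return SimulatedCohort(beta=beta_df, detection_p=detp_df,
                           sample_sheet=sheet, truth=truth)
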