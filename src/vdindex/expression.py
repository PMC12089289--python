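"""Normalization, filtering, paired differential expression and MDS.

The differential-expression front end is a paired moderated-t on
TMM-normalized log2 CPM: per-gene variances are shrunk toward a trend over
average expression with an empirical-Bayes prior (scaled inverse chi-square,
prior df estimated from the spread of log residual variances), and genes can
additionally be tested against a fold-change threshold tau with a shifted-t
construction so that "significant" means |log2FC| credibly exceeds tau
rather than merely differing from zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .io import CohortValidationError, CountMatrix, GeneAnnotation

__all__ = [
    "CPMMatrix",
    "DETable",
    "FoldChangeMatrix",
    "MDSEmbedding",
    "cpm",
    "filter_genes",
    "tmm_factors",
    "participant_log2fc",
    "paired_de",
    "bh_adjust",
    "mds_embed",
]

DE_COLUMNS = [
    "gene_id",
    "log2fc",
    "p_raw",
    "fdr",
    "p_treat",
    "direction",
    "sig_p05",
    "sig_lfc",
    "sig_fdr",
]


@dataclass
class CPMMatrix:
    """Counts-per-million with optional TMM effective-library correction."""

    values: pd.DataFrame  # genes x samples, float CPM
    norm_factors: pd.Series  # per-sample TMM factor (1.0 when not applied)
    sample_map: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_at(self, timepoint: str) -> list[str]:
        return list(
            self.sample_map.index[self.sample_map["timepoint"] == timepoint]
        )

    def subset_genes(self, gene_ids) -> "CPMMatrix":
        return CPMMatrix(
            values=self.values.loc[list(gene_ids)],
            norm_factors=self.norm_factors,
            sample_map=self.sample_map,
        )


@dataclass
class FoldChangeMatrix:
    """Per-participant log2((CPM_d1 + c) / (CPM_d0 + c)); participants x genes."""

    values: pd.DataFrame
    prior: float

    @property
    def participant_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class MDSEmbedding:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x k
    pairwise_distances: pd.DataFrame
    eigenvalues: np.ndarray


def cpm(counts: CountMatrix, norm_factors: pd.Series | None = None) -> CPMMatrix:
    """Counts per million: ``counts * 1e6 / library_size``.

    With ``norm_factors`` given, effective library sizes
    ``library_size * factor`` are used (TMM-adjusted CPM).
    """
    lib = counts.library_sizes.astype(float)
    if (lib == 0).any():
        bad = list(lib.index[lib == 0])
        raise CohortValidationError(f"all-zero samples: {bad}")
    if norm_factors is None:
        factors = pd.Series(1.0, index=lib.index)
    else:
        factors = norm_factors.loc[lib.index].astype(float)
    values = counts.counts.astype(float) * 1e6 / (lib * factors)
    return CPMMatrix(values=values, norm_factors=factors, sample_map=counts.sample_map)


def filter_genes(
    cpm_matrix: CPMMatrix,
    annotation: GeneAnnotation,
    threshold: float = 10.0,
) -> pd.Series:
    """Expressed protein-coding gene mask.

    A gene is kept iff it is protein-coding, has genomic position
    information, and its mean CPM is strictly above ``threshold`` at d0
    samples and, separately, at d1 samples.
    """
    if not annotation.covers(cpm_matrix.gene_ids):
        raise CohortValidationError("annotation does not cover all genes")
    ann = annotation.frame.loc[cpm_matrix.gene_ids]
    coding = (ann["biotype"] == "protein_coding") & ann["has_position"]
    mean_d0 = cpm_matrix.values[cpm_matrix.samples_at("d0")].mean(axis=1)
    mean_d1 = cpm_matrix.values[cpm_matrix.samples_at("d1")].mean(axis=1)
    return coding & (mean_d0 > threshold) & (mean_d1 > threshold)


# ---------------------------------------------------------------------------
# TMM normalization (trimmed mean of M-values)
# ---------------------------------------------------------------------------


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float = 0.30, trim_a: float = 0.05) -> float:
    """Log2 TMM factor of one sample against the reference sample.

    M/A values over genes expressed in both samples, doubly trimmed (30% on
    M, 5% on A, keeping the intersection), combined by a precision-weighted
    mean of M with the standard binomial delta-method weights.
    """
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        raise CohortValidationError("sample shares no expressed genes with reference")
    obs = obs[keep].astype(float)
    ref = ref[keep].astype(float)
    p_obs = obs / n_obs
    p_ref = ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[finite], a[finite], w[finite]
    if len(m) == 0:
        return 0.0
    # degenerate: all M identical (pure depth shift) -> factor 0 in log2
    if np.ptp(m) < 1e-10:
        return 0.0
    lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
    lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
    keep2 = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    if not keep2.any():
        return 0.0
    return float(np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2]))


def tmm_factors(counts: CountMatrix, reference: str = "auto") -> pd.Series:
    """Per-sample TMM normalization factors.

    ``reference="auto"`` picks the sample whose upper-quartile CPM is
    closest to the mean upper quartile. Factors are rescaled so their log
    mean is zero; multiply library sizes by them to obtain effective sizes.
    """
    mat = counts.counts.to_numpy(dtype=float)
    if mat.shape[1] < 2:
        raise CohortValidationError("TMM needs at least 2 samples")
    lib = mat.sum(axis=0)
    cpm_raw = mat * 1e6 / lib
    if reference == "auto":
        q75 = np.array(
            [np.quantile(cpm_raw[:, j][cpm_raw[:, j] > 0], 0.75)
             if (cpm_raw[:, j] > 0).any() else 0.0
             for j in range(mat.shape[1])]
        )
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    else:
        sample_ids = list(counts.counts.columns)
        if reference not in sample_ids:
            raise CohortValidationError(f"unknown reference sample {reference!r}")
        ref_idx = sample_ids.index(reference)
    ref = mat[:, ref_idx]
    n_ref = lib[ref_idx]
    log2f = np.array(
        [_tmm_pair(mat[:, j], ref, lib[j], n_ref) for j in range(mat.shape[1])]
    )
    log2f -= log2f.mean()  # geometric mean of factors = 1
    return pd.Series(2.0 ** log2f, index=counts.counts.columns, name="tmm_factor")


# ---------------------------------------------------------------------------
# per-participant fold changes
# ---------------------------------------------------------------------------


def participant_log2fc(
    cpm_matrix: CPMMatrix, prior: float | pd.Series = 0.5
) -> FoldChangeMatrix:
    """Per-participant log2 fold change d1 vs d0 with a pseudo-CPM offset.

    ``prior`` may be a per-gene Series; rescaled expression (e.g. after
    cross-cohort harmonization) needs the offset rescaled by the same
    factor for the scaling to cancel exactly in the ratio.
    """
    if isinstance(prior, pd.Series):
        prior_vec = prior.loc[cpm_matrix.gene_ids].to_numpy(dtype=float)
    else:
        prior_vec = float(prior)
    pids: list[str] = []
    for pid in cpm_matrix.sample_map["participant_id"]:
        if pid not in pids:
            pids.append(pid)
    m = cpm_matrix.sample_map
    rows = {}
    for pid in pids:
        mine = m[m["participant_id"] == pid]
        tps = sorted(mine["timepoint"])
        if tps != ["d0", "d1"]:
            raise CohortValidationError(f"participant {pid} is not d0/d1 paired")
        s0 = mine.index[mine["timepoint"] == "d0"][0]
        s1 = mine.index[mine["timepoint"] == "d1"][0]
        rows[pid] = np.log2(
            (cpm_matrix.values[s1].to_numpy() + prior_vec)
            / (cpm_matrix.values[s0].to_numpy() + prior_vec)
        )
    values = pd.DataFrame.from_dict(rows, orient="index", columns=cpm_matrix.gene_ids)
    scalar_prior = float(np.mean(prior_vec)) if np.ndim(prior_vec) else float(prior_vec)
    return FoldChangeMatrix(values=values.loc[pids], prior=scalar_prior)


# ---------------------------------------------------------------------------
# moderated paired t with fold-change-threshold (TREAT-style) testing
# ---------------------------------------------------------------------------


def _fit_variance_prior(s2: np.ndarray, df: float, abundance: np.ndarray):
    """Estimate (prior_df, prior_var_trend) for scaled-inv-chi2 shrinkage.

    The trend of log variances over average abundance is a running-median
    smoother; the prior df comes from matching the excess spread of
    ``log(s2)`` about the trend against the theoretical ``trigamma(df/2)``
    sampling spread — the standard moments fit of an F-distribution.
    """
    s2 = np.maximum(s2, 1e-12)
    z = np.log(s2)
    order = np.argsort(abundance, kind="stable")
    zs = z[order]
    n = len(z)
    win = max(min(n // 10 * 2 + 1, 501), 1)
    if n >= 30:
        trend_sorted = (
            pd.Series(zs).rolling(win, center=True, min_periods=1).median().to_numpy()
        )
    else:
        trend_sorted = np.full(n, np.median(zs))
    trend = np.empty(n)
    trend[order] = trend_sorted
    e = z - trend - special.digamma(df / 2.0) + np.log(df / 2.0)
    ev = np.var(e, ddof=1) if n > 1 else 0.0
    excess = ev - special.polygamma(1, df / 2.0)
    if excess <= 1e-8:
        prior_df = np.inf
    else:
        # solve trigamma(d0/2) = excess for d0
        def f(x):
            return special.polygamma(1, x / 2.0) - excess

        try:
            prior_df = optimize.brentq(f, 1e-3, 1e7)
        except ValueError:
            prior_df = np.inf
    # prior variance along the trend, bias-corrected for E[log chi2]
    if np.isfinite(prior_df):
        correction = np.log(prior_df / 2.0) - special.digamma(prior_df / 2.0)
    else:
        correction = 0.0
    prior_var = np.exp(trend + np.mean(e) + correction)
    return prior_df, prior_var


def paired_de(cpm_matrix: CPMMatrix, tau: float = 0.25, prior: float = 0.5,
              alpha: float = 0.05, fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Paired differential expression d1 vs d0 with threshold testing.

    Per gene the effect is the mean over participants of the paired
    log2(CPM + prior) difference; its variance is moderated by
    empirical-Bayes shrinkage toward a trend over average log2 CPM. p_raw is
    the two-sided moderated-t p-value, p_treat the shifted-t p-value for
    H0: |effect| <= tau, and fdr the Benjamini-Hochberg adjustment of p_raw.
    """
    fc = participant_log2fc(cpm_matrix, prior=prior)
    deltas = fc.values.to_numpy()  # participants x genes
    n = deltas.shape[0]
    if n < 3:
        raise CohortValidationError("paired DE needs at least 3 pairs")
    df = n - 1
    effect = deltas.mean(axis=0)
    s2 = deltas.var(axis=0, ddof=1)
    abundance = np.log2(cpm_matrix.values.to_numpy() + prior).mean(axis=1)
    prior_df, prior_var = _fit_variance_prior(s2, df, abundance)
    if np.isfinite(prior_df):
        s2_post = (prior_df * prior_var + df * s2) / (prior_df + df)
        df_total = df + prior_df
    else:
        s2_post = prior_var
        df_total = np.inf
    se = np.sqrt(s2_post / n)
    se = np.maximum(se, 1e-300)
    t = effect / se
    p_raw = 2.0 * stats.t.sf(np.abs(t), df_total)
    # shifted-t threshold test: H0 |effect| <= tau
    t_right = (np.abs(effect) - tau) / se
    t_left = (np.abs(effect) + tau) / se
    p_treat = stats.t.sf(t_right, df_total) + stats.t.sf(t_left, df_total)
    p_treat = np.minimum(p_treat, 1.0)
    fdr = bh_adjust(p_raw)
    out = pd.DataFrame(
        {
            "gene_id": cpm_matrix.gene_ids,
            "log2fc": effect,
            "p_raw": p_raw,
            "fdr": fdr,
            "p_treat": p_treat,
            "direction": np.where(effect >= 0, "up", "down"),
            "sig_p05": p_raw < alpha,
            "sig_lfc": p_treat < alpha,
            "sig_fdr": fdr < fdr_alpha,
        }
    )
    # deterministic ordering: p ascending, gene id as tie-break
    out = out.sort_values(["p_raw", "gene_id"], kind="stable").reset_index(drop=True)
    return out[DE_COLUMNS]


class DETable:
    """Column contract and validation helpers for DE result tables."""

    COLUMNS = DE_COLUMNS

    @staticmethod
    def validate(df: pd.DataFrame) -> pd.DataFrame:
        missing = set(DE_COLUMNS) - set(df.columns)
        if missing:
            raise CohortValidationError(f"DE table missing columns: {sorted(missing)}")
        for col in ("p_raw", "fdr", "p_treat"):
            vals = df[col].to_numpy(dtype=float)
            if ((vals < 0) | (vals > 1)).any():
                raise CohortValidationError(f"{col} outside [0, 1]")
        return df

    @staticmethod
    def significant_sets(df: pd.DataFrame) -> dict[str, set[str]]:
        """The three nested significance gene sets used downstream."""
        DETable.validate(df)
        return {
            "p05": set(df.loc[df["sig_p05"], "gene_id"]),
            "lfc": set(df.loc[df["sig_p05"] & df["sig_lfc"], "gene_id"]),
            "fdr": set(df.loc[df["sig_fdr"], "gene_id"]),
        }


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR, order-preserving and capped at 1."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise CohortValidationError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# MDS on RMSD-of-log2FC distances
# ---------------------------------------------------------------------------


def mds_embed(cpm_matrix: CPMMatrix, gene_subset, k: int = 2,
              prior: float = 0.5) -> MDSEmbedding:
    """Classical (Torgerson) MDS of samples.

    The pairwise distance between samples is the root mean square deviation
    of per-gene log2 CPM over ``gene_subset`` — i.e. the typical log2 fold
    change between the two samples on those genes.
    """
    gene_subset = list(gene_subset)
    if not gene_subset:
        raise CohortValidationError("MDS gene subset is empty")
    samples = cpm_matrix.sample_ids
    if len(samples) < 3:
        raise CohortValidationError("MDS needs at least 3 samples")
    logv = np.log2(cpm_matrix.values.loc[gene_subset].to_numpy() + prior)
    diffs = logv[:, :, None] - logv[:, None, :]
    d = np.sqrt(np.mean(diffs**2, axis=0))
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    idx = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[idx], eigvec[:, idx]
    rank = int(np.sum(eigval > max(1e-9, 1e-9 * abs(eigval[0]))))
    if k > max(rank, 1):
        raise CohortValidationError(f"k={k} exceeds achievable rank {rank}")
    coords = eigvec[:, :k] * np.sqrt(np.maximum(eigval[:k], 0.0))
    return MDSEmbedding(
        sample_ids=samples,
        coordinates=coords,
        pairwise_distances=pd.DataFrame(d, index=samples, columns=samples),
        eigenvalues=eigval,
    )
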