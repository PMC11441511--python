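"""Region-level RRBS differential methylation.

Per-CpG methylated/unmethylated read counts (Bismark-style coverage files)
are filtered for depth, chained into regions (consecutive CpGs within
200 bp), filtered for a minimum methylation level, and tested per region
with a binomial-logistic GLM: ``logit(pi_j) = beta0 + beta1 * cond_j`` fitted
by iteratively reweighted least squares, with a likelihood-ratio test of
``beta1 = 0`` against chi-square(1).  DMRs are regions with BH-adjusted
p <= 0.01 and raw p <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MethylationDataset",
    "RegionSet",
    "read_coverage",
    "filter_low_coverage",
    "aggregate_regions",
    "filter_regions_by_methylation",
    "binomial_glm_lrt",
    "lrt_regions",
    "adjust_pvalues",
    "call_dmrs",
    "regions_to_bed",
]

COVERAGE_COLUMNS = ["chrom", "start", "end", "meth_pct", "count_m", "count_u"]


def read_coverage(path) -> pd.DataFrame:
    """Parse a Bismark-style coverage file for one sample.

    Tab-separated columns: chrom, start, end, methylation percentage,
    methylated count, unmethylated count (1-based, start == end for a CpG).
    The percentage is recomputed from the counts and must agree within 0.1.
    """
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 tab-separated fields, "
                                 f"got {len(fields)}")
            chrom, start, end, pct, m, u = fields
            try:
                start, pct, m, u = int(start), float(pct), int(m), int(u)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed field ({exc})") from None
            if m < 0 or u < 0:
                raise ValueError(f"{path}:{lineno}: negative count")
            if m + u == 0:
                raise ValueError(f"{path}:{lineno}: zero coverage")
            expected = 100.0 * m / (m + u)
            if abs(pct - expected) > 0.1:
                raise ValueError(
                    f"{path}:{lineno}: methylation percentage {pct} inconsistent "
                    f"with counts {m}/{m + u} (expected {expected:.4f})")
            rows.append((chrom, start, m, u))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "m", "u"])
    return df.sort_values(["chrom", "pos"]).reset_index(drop=True)


@dataclass
class MethylationDataset:
    """Per-CpG counts across samples.

    ``loci`` holds (chrom, pos); ``m`` and ``t`` are loci x sample matrices
    of methylated and total read counts; ``conditions`` maps each sample to
    its condition label.
    """

    loci: pd.DataFrame
    m: pd.DataFrame
    t: pd.DataFrame
    conditions: dict

    @classmethod
    def from_coverage_files(cls, sample_paths: dict, conditions: dict,
                            how: str = "inner") -> "MethylationDataset":
        """Load one coverage file per sample and align loci across samples.

        ``how='inner'`` keeps loci observed in every sample (a locus absent
        from a sample has no Bismark record, so no coverage there).
        """
        m_cols, t_cols = {}, {}
        for sample, path in sample_paths.items():
            df = read_coverage(path).set_index(["chrom", "pos"])
            m_cols[sample] = df["m"]
            t_cols[sample] = df["m"] + df["u"]
        m = pd.concat(m_cols, axis=1, join=how).fillna(0).astype(int)
        t = pd.concat(t_cols, axis=1, join=how).fillna(0).astype(int)
        m = m.sort_index()
        t = t.sort_index()
        loci = m.index.to_frame(index=False)
        missing = set(m.columns) - set(conditions)
        if missing:
            raise ValueError(f"samples without a condition: {sorted(missing)}")
        return cls(loci, m.reset_index(drop=True), t.reset_index(drop=True),
                   dict(conditions))

    @property
    def samples(self) -> list:
        return list(self.m.columns)

    def __len__(self) -> int:
        return len(self.loci)


def filter_low_coverage(ds: MethylationDataset, min_cov: int = 25,
                        mode: str = "per_sample") -> MethylationDataset:
    """Drop loci below the coverage threshold.

    ``per_sample`` (default) keeps a locus only when coverage >= ``min_cov``
    in every sample; ``pooled`` thresholds the summed coverage instead.
    """
    if min_cov < 0:
        raise ValueError("min_cov must be >= 0")
    if mode == "per_sample":
        keep = (ds.t >= min_cov).all(axis=1)
    elif mode == "pooled":
        keep = ds.t.sum(axis=1) >= min_cov
    else:
        raise ValueError("mode must be 'per_sample' or 'pooled'")
    idx = keep.to_numpy()
    return MethylationDataset(ds.loci[idx].reset_index(drop=True),
                              ds.m[idx].reset_index(drop=True),
                              ds.t[idx].reset_index(drop=True),
                              dict(ds.conditions))


@dataclass
class RegionSet:
    """Chained CpG regions with per-sample summed counts.

    ``regions`` holds chrom/start/end/n_loci; ``m`` and ``t`` are
    region x sample matrices of summed methylated and total counts.
    """

    regions: pd.DataFrame
    m: pd.DataFrame
    t: pd.DataFrame
    conditions: dict

    def methylation_fraction(self) -> pd.DataFrame:
        return self.m / self.t

    def __len__(self) -> int:
        return len(self.regions)

    def _subset(self, idx: np.ndarray) -> "RegionSet":
        return RegionSet(self.regions[idx].reset_index(drop=True),
                         self.m[idx].reset_index(drop=True),
                         self.t[idx].reset_index(drop=True),
                         dict(self.conditions))


def aggregate_regions(ds: MethylationDataset, max_gap: int = 200) -> RegionSet:
    """Greedy chaining of sorted CpGs into regions.

    A locus joins the open region when it is on the same chromosome and at
    most ``max_gap`` bases downstream of the previous member; region counts
    are the sums over member loci.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    chroms = ds.loci["chrom"].to_numpy()
    pos = ds.loci["pos"].to_numpy()
    if len(ds) == 0:
        empty = pd.DataFrame(columns=["chrom", "start", "end", "n_loci"])
        return RegionSet(empty, ds.m.iloc[:0], ds.t.iloc[:0], dict(ds.conditions))
    new_region = np.ones(len(ds), dtype=bool)
    same = (chroms[1:] == chroms[:-1]) & (pos[1:] - pos[:-1] <= max_gap)
    new_region[1:] = ~same
    region_id = np.cumsum(new_region) - 1

    regions = (pd.DataFrame({"chrom": chroms, "pos": pos, "rid": region_id})
               .groupby("rid")
               .agg(chrom=("chrom", "first"), start=("pos", "min"),
                    end=("pos", "max"), n_loci=("pos", "size"))
               .reset_index(drop=True))
    m = ds.m.groupby(region_id).sum().reset_index(drop=True)
    t = ds.t.groupby(region_id).sum().reset_index(drop=True)
    return RegionSet(regions, m, t, dict(ds.conditions))


def filter_regions_by_methylation(rs: RegionSet, min_meth: float = 0.5,
                                  min_rep_frac: float = 0.75) -> RegionSet:
    """Keep regions methylated in the majority of replicates of a condition.

    A region survives iff for some condition, the fraction of that
    condition's replicates with region-level M/T >= ``min_meth`` exceeds
    ``min_rep_frac``.
    """
    frac = rs.methylation_fraction()
    keep = np.zeros(len(rs), dtype=bool)
    labels = set(rs.conditions.values())
    for cond in labels:
        samples = [s for s in rs.m.columns if rs.conditions[s] == cond]
        if not samples:
            raise ValueError(f"condition {cond!r} has zero replicates")
        prop = (frac[samples] >= min_meth).mean(axis=1)
        keep |= (prop > min_rep_frac).to_numpy()
    return rs._subset(keep)


# ---------------------------------------------------------------------------
# Binomial GLM + likelihood-ratio test


def _binomial_deviance(m, t, pi):
    m = np.asarray(m, float)
    t = np.asarray(t, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(m > 0, m * np.log(m / (t * pi)), 0.0)
        term2 = np.where(t - m > 0, (t - m) * np.log((t - m) / (t * (1.0 - pi))), 0.0)
    return 2.0 * float(np.sum(term1 + term2))


def _irls(m, t, X, tol: float = 1e-8, max_iter: int = 50):
    """Fit a binomial-logistic GLM by IRLS; returns (beta, deviance, converged).

    Observed proportions are clamped to [0.5/T, 1 - 0.5/T] so complete
    separation still yields finite estimates.
    """
    m = np.asarray(m, float)
    t = np.asarray(t, float)
    X = np.asarray(X, float)
    y = np.clip(m / t, 0.5 / t, 1.0 - 0.5 / t)
    beta = np.zeros(X.shape[1])
    dev = np.inf
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        pi = 1.0 / (1.0 + np.exp(-eta))
        pi = np.clip(pi, 1e-12, 1.0 - 1e-12)
        w = t * pi * (1.0 - pi)
        z = eta + (y - pi) / (pi * (1.0 - pi))
        xtw = X.T * w
        beta = np.linalg.solve(xtw @ X, xtw @ z)
        new_dev = _binomial_deviance(np.clip(y * t, 0.5, t - 0.5), t,
                                     1.0 / (1.0 + np.exp(-(X @ beta))))
        if abs(dev - new_dev) < tol:
            dev = new_dev
            converged = True
            break
        dev = new_dev
    return beta, dev, converged


@dataclass
class DMRResult:
    beta0: float
    beta1: float
    lrt: float
    p: float
    converged: bool


def binomial_glm_lrt(m: Sequence[float], t: Sequence[float],
                     condition: Sequence[int]) -> DMRResult:
    """Likelihood-ratio test of a condition effect on region methylation.

    ``m``/``t`` are per-sample methylated/total counts for one region;
    ``condition`` codes the two conditions as 0/1.  The statistic is
    deviance(null) - deviance(full), referred to chi-square with 1 df.
    """
    m = np.asarray(m, float)
    t = np.asarray(t, float)
    cond = np.asarray(condition, float)
    if set(np.unique(cond)) - {0.0, 1.0}:
        raise ValueError("condition must be coded 0/1")
    if len(np.unique(cond)) != 2:
        raise ValueError("need both conditions represented")
    if np.any(t <= 0):
        raise ValueError("every sample needs positive total counts in the region")
    X_full = np.column_stack([np.ones_like(cond), cond])
    X_null = np.ones((len(cond), 1))
    beta_full, dev_full, conv_full = _irls(m, t, X_full)
    beta_null, dev_null, conv_null = _irls(m, t, X_null)
    lrt = max(dev_null - dev_full, 0.0)
    p = float(stats.chi2.sf(lrt, df=1))
    return DMRResult(float(beta_full[0]), float(beta_full[1]), lrt, p,
                     conv_full and conv_null)


def adjust_pvalues(pvals, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("bh", "fdr_bh"):
        raise ValueError("only Benjamini-Hochberg ('bh') is supported")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def lrt_regions(rs: RegionSet, condition_order: Optional[Sequence[str]] = None
                 ) -> pd.DataFrame:
    """Run the per-region LRT across a RegionSet and adjust p-values.

    Returns the region table with per-condition mean methylation, beta1
    (log-odds condition effect), lrt, p, p_adjust and is_dmr columns.
    """
    labels = sorted(set(rs.conditions.values())) if condition_order is None \
        else list(condition_order)
    if len(labels) != 2:
        raise ValueError(f"exactly two conditions required, got {labels}")
    samples = list(rs.m.columns)
    cond = np.array([labels.index(rs.conditions[s]) for s in samples])

    out = rs.regions.copy()
    frac = rs.methylation_fraction()
    for j, lab in enumerate(labels):
        cols = [s for s, c in zip(samples, cond) if c == j]
        out[f"meth_{lab}"] = frac[cols].mean(axis=1)

    res = [binomial_glm_lrt(rs.m.iloc[i].to_numpy(), rs.t.iloc[i].to_numpy(), cond)
           for i in range(len(rs))]
    out["beta1"] = [r.beta1 for r in res]
    out["lrt"] = [r.lrt for r in res]
    out["p"] = [r.p for r in res]
    out["converged"] = [r.converged for r in res]
    out["p_adjust"] = adjust_pvalues(out["p"].to_numpy()) if len(out) else []
    return call_dmrs(out)


def call_dmrs(results: pd.DataFrame, max_p_adjust: float = 0.01,
              max_p: float = 0.05) -> pd.DataFrame:
    """Flag DMRs: p_adjust <= 0.01 and raw p <= 0.05 (both required)."""
    out = results.copy()
    out["is_dmr"] = (out["p_adjust"] <= max_p_adjust) & (out["p"] <= max_p)
    return out


def regions_to_bed(results: pd.DataFrame, dmr_only: bool = True) -> pd.DataFrame:
    """BED export (0-based half-open: start-1, end) of regions or DMRs."""
    df = results[results["is_dmr"]] if dmr_only else results
    return pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["start"] - 1,
        "end": df["end"],
        "name": [f"region_{i}" for i in df.index],
        "score": np.minimum(1000, (-10.0 * np.log10(
            np.clip(df["p_adjust"].to_numpy(float), 1e-100, 1.0))).astype(int)),
    }).reset_index(drop=True)
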