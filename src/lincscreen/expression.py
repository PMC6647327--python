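"""Count normalization, differential expression and polysome-association shifts.

The workflow mirrors the standard bulk RNA-seq treatment of a multi-condition
design (here 12 conditions x 3 replicates, two RNA fractions):

* size factors by the median-of-ratios method (the DESeq family estimator),
* a simplified per-contrast negative-binomial Wald test for steady-state
  differential expression (common method-of-moments dispersion, BH-adjusted
  p-values) — deliberately plainer than shrinkage-based callers but with the
  same interface (fold change, adjusted p),
* a replicate-level log-ratio t-test for shifts in polysome association
  (polysomal/total), the translation-efficiency proxy,
* Pearson correlation of condition-level mean expression profiles.

Fold changes are reported A-relative-to-B for a contrast ``(A, B)``:
down-regulation in A prints as FC < 1.
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

_SAMPLE_RE = re.compile(r"^(?P<condition>.+)_(?P<fraction>total|polysomal)_rep(?P<replicate>\d+)$")

PSEUDOCOUNT = 0.5
DISPERSION_FLOOR = 1e-8


@dataclass
class CountMatrix:
    """Loci x samples counts plus the sample design.

    ``data`` holds raw integers or normalized reals; ``samples`` is indexed by
    sample name with columns condition/fraction/replicate; ``size_factors`` is
    set after normalization (normalized = raw / size_factor).
    """

    data: pd.DataFrame
    samples: pd.DataFrame
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if list(self.data.columns) != list(self.samples.index):
            raise ValueError("sample metadata does not match count matrix columns")
        if self.data.isna().any().any():
            raise ValueError("count matrix contains missing cells")

    @property
    def loci(self) -> list[str]:
        return list(self.data.index)

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.samples["condition"]:
            if c not in seen:
                seen.append(c)
        return seen

    def samples_for(self, condition: str) -> list[str]:
        mask = self.samples["condition"] == condition
        if not mask.any():
            raise ValueError(f"condition {condition!r} absent from design")
        return list(self.samples.index[mask])

    def condition_means(self) -> pd.DataFrame:
        """Mean over replicates per condition (loci x conditions)."""
        cols = {c: self.data[self.samples_for(c)].mean(axis=1) for c in self.conditions()}
        return pd.DataFrame(cols)

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path: str | os.PathLike) -> None:
        df = self.data.copy()
        df.index.name = "locus"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "CountMatrix":
        data = pd.read_csv(path, sep="\t", index_col=0)
        return cls(data=data, samples=parse_sample_names(list(data.columns)))


def parse_sample_names(names: list[str]) -> pd.DataFrame:
    """Decode ``<condition>_<fraction>_rep<k>`` sample names into a design table."""
    rows = []
    for name in names:
        m = _SAMPLE_RE.match(name)
        if not m:
            raise ValueError(f"sample name {name!r} does not encode condition/fraction/replicate")
        rows.append((name, m["condition"], m["fraction"], int(m["replicate"])))
    return pd.DataFrame(rows, columns=["sample", "condition", "fraction", "replicate"]).set_index("sample")


def make_count_matrix(
    values: np.ndarray, loci: list[str], sample_names: list[str]
) -> CountMatrix:
    data = pd.DataFrame(values, index=loci, columns=sample_names)
    return CountMatrix(data=data, samples=parse_sample_names(sample_names))


# ---------------------------------------------------------------------------
# Normalization


def normalize_counts(raw: CountMatrix) -> CountMatrix:
    """Median-of-ratios normalization.

    Size factor for sample j is the median over loci (restricted to loci with
    all-positive counts) of count_ij / geometric-mean_i; normalized counts are
    raw / size factor.
    """
    counts = raw.data.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples to normalize")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no locus has positive counts in every sample; consider a pseudo-reference "
            "(e.g. add a pseudocount) before normalization"
        )
    logs = np.log(counts[positive])
    log_geo = logs.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logs - log_geo, axis=0))
    size_factors = pd.Series(sf, index=raw.data.columns)
    return CountMatrix(
        data=raw.data / sf,
        samples=raw.samples.copy(),
        size_factors=size_factors,
    )


def _ensure_normalized(mat: CountMatrix) -> CountMatrix:
    return mat if mat.size_factors is not None else normalize_counts(mat)


# ---------------------------------------------------------------------------
# Differential expression (steady state)


def _mom_dispersion(group_values: list[np.ndarray]) -> float:
    """Common negative-binomial dispersion via pooled method of moments.

    Solving E[var] = mean + alpha*mean^2 across all loci and replicate groups
    in one precision-weighted ratio, alpha = sum(var - mean) / sum(mean^2),
    floored at ``DISPERSION_FLOOR``. A single shared dispersion keeps the
    Wald test calibrated at small replicate numbers, where per-locus
    estimates are far too noisy, and the mean^2 weighting makes the pooled
    estimate nearly unbiased (the per-locus median is biased low by the
    skew of three-replicate variance estimates).
    """
    num = 0.0
    den = 0.0
    for vals in group_values:
        mu = vals.mean(axis=1)
        var = vals.var(axis=1, ddof=1)
        keep = mu > 0
        num += float((var[keep] - mu[keep]).sum())
        den += float((mu[keep] ** 2).sum())
    if den == 0.0:
        return DISPERSION_FLOOR
    return max(num / den, DISPERSION_FLOOR)


def differential_expression(
    mat: CountMatrix,
    contrast: tuple[str, str],
    min_count: float = 0.0,
    dispersion: float | None = None,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-locus fold change and NB Wald test for one contrast ``(A, B)``.

    FC = (mean normalized in A + pc) / (mean normalized in B + pc). The Wald
    statistic divides log FC by its delta-method standard error under a
    negative binomial with the common dispersion; p-values are two-sided
    normal tails, BH-adjusted across all loci tested within the contrast.
    """
    cond_a, cond_b = contrast
    norm = _ensure_normalized(mat)
    va = norm.data[norm.samples_for(cond_a)].to_numpy(dtype=float)
    vb = norm.data[norm.samples_for(cond_b)].to_numpy(dtype=float)
    n_a, n_b = va.shape[1], vb.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least two replicates per condition")

    mu_a = va.mean(axis=1)
    mu_b = vb.mean(axis=1)
    keep = (mu_a >= min_count) | (mu_b >= min_count)

    alpha = dispersion if dispersion is not None else _mom_dispersion([va[keep], vb[keep]])
    fc = (mu_a + pseudocount) / (mu_b + pseudocount)
    log_fc = np.log(fc)
    se = np.sqrt(
        (1.0 / n_a) * (1.0 / (mu_a + pseudocount) + alpha)
        + (1.0 / n_b) * (1.0 / (mu_b + pseudocount) + alpha)
    )
    z = log_fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))

    res = pd.DataFrame(
        {
            "locus": norm.data.index,
            "mean_a": mu_a,
            "mean_b": mu_b,
            "fc": fc,
            "log2_fc": log_fc / np.log(2.0),
            "dispersion": alpha,
            "p": p,
        }
    ).set_index("locus")
    res = res[keep]
    res["padj"] = multipletests(res["p"].to_numpy(), method="fdr_bh")[1]
    return res


# ---------------------------------------------------------------------------
# Polysome-association shift


def polysome_shift(
    total: CountMatrix,
    polysomal: CountMatrix,
    contrast: tuple[str, str],
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Change in polysome association (polysomal/total ratio) between conditions.

    Per replicate, PA = log((polysomal + pc) / (total + pc)) on normalized
    counts; the PA fold change is exp(mean PA in A - mean PA in B) and the
    p-value a two-sample t-test on replicate-level PA values, BH-adjusted.
    """
    if list(total.data.index) != list(polysomal.data.index):
        extra = sorted(set(total.data.index).symmetric_difference(polysomal.data.index))
        raise ValueError(f"total and polysomal matrices disagree on loci: {extra[:10]}")
    if "polysomal" not in set(polysomal.samples["fraction"]):
        raise ValueError("polysomal matrix carries no 'polysomal' fraction labels")

    t_norm = _ensure_normalized(total)
    p_norm = _ensure_normalized(polysomal)

    def _pa(cond: str) -> np.ndarray:
        t_cols = t_norm.samples_for(cond)
        p_cols = p_norm.samples_for(cond)
        t_rep = t_norm.samples.loc[t_cols, "replicate"]
        p_rep = p_norm.samples.loc[p_cols, "replicate"]
        t_by_rep = {r: c for c, r in t_rep.items()}
        p_by_rep = {r: c for c, r in p_rep.items()}
        reps = sorted(set(t_by_rep) & set(p_by_rep))
        if not reps:
            raise ValueError(f"no matched replicates between fractions for condition {cond!r}")
        t_vals = t_norm.data[[t_by_rep[r] for r in reps]].to_numpy(dtype=float)
        p_vals = p_norm.data[[p_by_rep[r] for r in reps]].to_numpy(dtype=float)
        return np.log((p_vals + pseudocount) / (t_vals + pseudocount))

    pa_a = _pa(contrast[0])
    pa_b = _pa(contrast[1])
    pa_fc = np.exp(pa_a.mean(axis=1) - pa_b.mean(axis=1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, p = stats.ttest_ind(pa_a, pa_b, axis=1)
    p = np.where(np.isfinite(p), p, 1.0)

    res = pd.DataFrame(
        {"locus": t_norm.data.index, "pa_fc": pa_fc, "p": p}
    ).set_index("locus")
    res["padj"] = multipletests(res["p"].to_numpy(), method="fdr_bh")[1]
    return res


# ---------------------------------------------------------------------------
# Expression-profile correlation


def pearson_profile(x, y) -> float:
    """Sample Pearson correlation of two condition-level mean profiles.

    Returns NaN (with a warning) for constant input rather than forcing +/-1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("profiles must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least three conditions for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant expression profile: Pearson correlation undefined")
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
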