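"""Multilevel statistics over fitted parameter ensembles.

Pooled best-fit parameter tables are screened for degeneracy structure with
a Spearman rank correlation matrix (pairs with |rho| > 0.2 highlighted);
grouped parameter distributions are compared at the experiment, cell or
trace level with a Kruskal-Wallis omnibus test followed by Dunn's (or
Tukey's) pairwise post-hoc; peak-amplitude histograms are fitted with the
4-parameter pseudo-Voigt profile; and the analytic time-to-peak is
correlated against event amplitude as a space-clamp diagnostic (somatic
events show no correlation).

By default pooled analyses use only the best fit per trace, to avoid
over-weighting low-noise traces that admit many good fits.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from .synthetic import PseudoVoigtParams, pseudo_voigt

__all__ = [
    "GroupedValues",
    "ComparisonMatrix",
    "UndefinedCorrelationError",
    "SPEARMAN_HIGHLIGHT",
    "spearman_matrix",
    "dunn_posthoc",
    "group_compare",
    "fit_pseudo_voigt",
    "peak_histogram",
    "time_to_peak_stats",
]

#: |rho| above which a parameter pair is highlighted as correlated
SPEARMAN_HIGHLIGHT = 0.2


class UndefinedCorrelationError(ValueError):
    """Correlation undefined (a constant column has no rank variation)."""


@dataclass(frozen=True)
class GroupedValues:
    """A named quantity split into labeled groups at some analysis level."""

    name: str
    groups: dict[str, np.ndarray]
    level: str = "experiment"  # experiment | cell | trace

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("groups must be nonempty")
        clean = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}
        for label, vals in clean.items():
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"group {label!r} contains non-finite values")
        object.__setattr__(self, "groups", clean)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, value: str, by: str,
                   level: str = "experiment") -> "GroupedValues":
        if by not in df.columns:
            raise KeyError(f"grouping column {by!r} not in table")
        groups = {str(k): sub[value].to_numpy(float)
                  for k, sub in df.groupby(by, sort=True)}
        return cls(name=value, groups=groups, level=level)


@dataclass(frozen=True)
class ComparisonMatrix:
    labels: tuple[str, ...]
    significant: np.ndarray  # boolean, symmetric, False diagonal
    pvalues: np.ndarray
    method: str
    alpha: float
    omnibus_stat: float
    omnibus_p: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.significant, index=self.labels,
                            columns=self.labels)


def spearman_matrix(table: pd.DataFrame,
                    highlight: float = SPEARMAN_HIGHLIGHT
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rank correlation matrix of a best-fit parameter table.

    Returns (rho, mask) DataFrames; ``mask`` is True where |rho| exceeds the
    highlight threshold off the diagonal.  Raises
    :class:`UndefinedCorrelationError` on constant columns, and requires at
    least 3 rows.
    """
    num = table.select_dtypes(include=[np.number])
    if len(num) < 3:
        raise ValueError(f"need at least 3 rows, got {len(num)}")
    constant = [c for c in num.columns if np.ptp(num[c].to_numpy()) == 0.0]
    if constant:
        raise UndefinedCorrelationError(
            f"constant column(s) {constant} have undefined rank correlation"
        )
    rho, _ = stats.spearmanr(num.to_numpy())
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    rho_df = pd.DataFrame(rho, index=num.columns, columns=num.columns)
    mask = rho_df.abs() > highlight
    np.fill_diagonal(mask.to_numpy(), False)
    return rho_df, mask


# ---------------------------------------------------------------------------
# Grouped comparisons

def dunn_posthoc(groups: dict[str, np.ndarray],
                 adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise rank-sum post-hoc after Kruskal-Wallis.

    Pooled ranks with tie correction; z_ij = (Rbar_i - Rbar_j) /
    sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j)) with tie term
    T = sum(t^3 - t) / (12 (N - 1)).  Two-sided p-values, adjusted
    family-wise (``bonferroni`` | ``holm`` | ``none``).
    """
    labels = list(groups)
    pooled = np.concatenate([groups[k] for k in labels])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    rank_means: dict[str, float] = {}
    sizes: dict[str, int] = {}
    pos = 0
    for k in labels:
        n_k = groups[k].size
        rank_means[k] = float(np.mean(ranks[pos:pos + n_k]))
        sizes[k] = n_k
        pos += n_k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (rank_means[a] - rank_means[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p})
    out = pd.DataFrame(rows)
    m = len(out)
    if adjust == "bonferroni":
        out["p_adj"] = np.minimum(out["p_raw"] * m, 1.0)
    elif adjust == "holm":
        order = np.argsort(out["p_raw"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p_raw"].iloc[idx])
            adj[idx] = min(running, 1.0)
        out["p_adj"] = adj
    elif adjust == "none":
        out["p_adj"] = out["p_raw"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out


def _tukey_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    labels = list(groups)
    values = np.concatenate([groups[k] for k in labels])
    codes = np.concatenate([[k] * groups[k].size for k in labels])
    res = pairwise_tukeyhsd(values, codes)
    frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    return pd.DataFrame({
        "group_a": frame["group1"].astype(str),
        "group_b": frame["group2"].astype(str),
        "p_adj": frame["p-adj"].astype(float),
    })


def group_compare(gv: GroupedValues, posthoc: str = "dunn",
                  alpha: float = 0.05,
                  adjust: str = "bonferroni") -> ComparisonMatrix:
    """Kruskal-Wallis omnibus plus pairwise post-hoc significance flags.

    Pairs are flagged only when the omnibus test itself is significant at
    ``alpha``.  Being rank-based (for the Dunn post-hoc), the outcome is
    invariant under any common strictly monotone transform of the values.
    """
    labels = tuple(sorted(gv.groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    for k in labels:
        if gv.groups[k].size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 values")
    arrays = [gv.groups[k] for k in labels]
    if all(np.ptp(np.concatenate(arrays)) == 0.0 for _ in (0,)):
        # identical constants in every group: trivially indistinguishable
        k_stat, k_p = 0.0, 1.0
    else:
        k_stat, k_p = stats.kruskal(*arrays)
    n = len(labels)
    sig = np.zeros((n, n), dtype=bool)
    pvals = np.ones((n, n))
    method = f"kruskal+{posthoc}"
    if k_p < alpha:
        if posthoc == "dunn":
            table = dunn_posthoc({k: gv.groups[k] for k in labels}, adjust=adjust)
            method = f"kruskal+dunn[{adjust}]"
        elif posthoc == "tukey":
            table = _tukey_posthoc({k: gv.groups[k] for k in labels})
        else:
            raise ValueError(f"unknown posthoc {posthoc!r}")
        index = {k: i for i, k in enumerate(labels)}
        for _, row in table.iterrows():
            i, j = index[str(row["group_a"])], index[str(row["group_b"])]
            pvals[i, j] = pvals[j, i] = row["p_adj"]
            if row["p_adj"] < alpha:
                sig[i, j] = sig[j, i] = True
    return ComparisonMatrix(
        labels=labels, significant=sig, pvalues=pvals, method=method,
        alpha=alpha, omnibus_stat=float(k_stat), omnibus_p=float(k_p),
    )


# ---------------------------------------------------------------------------
# Amplitude-distribution fitting

def peak_histogram(peaks: np.ndarray,
                   bin_width: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-width histogram of peak amplitudes, normalized as a density.

    Returns (bin_centers, heights)."""
    peaks = np.asarray(peaks, dtype=float)
    lo = bin_width * np.floor(peaks.min() / bin_width)
    hi = bin_width * np.ceil(peaks.max() / bin_width)
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    heights, edges = np.histogram(peaks, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, heights


def fit_pseudo_voigt(bin_centers: np.ndarray, heights: np.ndarray
                     ) -> tuple[PseudoVoigtParams, float]:
    """Least-squares pseudo-Voigt fit of a peak-amplitude histogram.

    Returns the fitted parameters and the Pearson correlation R between the
    fitted curve and the bin heights.  Requires at least 8 bins with mass.
    """
    x = np.asarray(bin_centers, dtype=float)
    y = np.asarray(heights, dtype=float)
    if np.count_nonzero(y) < 8:
        raise ValueError("need at least 8 bins with mass")

    def f(xv, a, b, c, x0):
        return pseudo_voigt(xv, PseudoVoigtParams(a=a, b=b, c=c, x0=x0))

    i_max = int(np.argmax(y))
    half = y >= 0.5 * y[i_max]
    width0 = max((x[half].max() - x[half].min()) / 2.0, np.diff(x).min())
    p0 = [float(y[i_max]), float(width0), 0.5, float(x[i_max])]
    try:
        popt, _ = curve_fit(
            f, x, y, p0=p0,
            bounds=([1e-12, 1e-6, 0.0, x.min() - np.ptp(x)],
                    [np.inf, np.inf, 1.0, x.max() + np.ptp(x)]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"pseudo-Voigt fit did not converge: {exc}") from exc
    params = PseudoVoigtParams(a=float(popt[0]), b=float(popt[1]),
                               c=float(popt[2]), x0=float(popt[3]))
    fitted = pseudo_voigt(x, params)
    r = float(stats.pearsonr(fitted, y)[0])
    return params, r


# ---------------------------------------------------------------------------
# Space-clamp diagnostic

def time_to_peak_stats(time_to_peak: np.ndarray,
                       peak_amplitude: np.ndarray) -> tuple[float, float]:
    """Pearson correlation of time-to-peak against event peak amplitude.

    Somatic events show no correlation (p > 0.05); dendritic filtering would
    introduce one.  Raises on fewer than 3 pairs or a constant input.
    """
    ttp = np.asarray(time_to_peak, dtype=float)
    amp = np.asarray(peak_amplitude, dtype=float)
    if ttp.size != amp.size:
        raise ValueError("mismatched record counts")
    if ttp.size < 3:
        raise ValueError("need at least 3 matched records")
    if np.ptp(ttp) == 0.0 or np.ptp(amp) == 0.0:
        raise UndefinedCorrelationError("constant input has undefined correlation")
    r, p = stats.pearsonr(ttp, amp)
    return float(r), float(p)
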