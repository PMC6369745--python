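"""Recombination statistics: genetic map, proximal bias, spacing, G+C bias.

Genetic size of a chromosome over a set of haploid progeny is
``100 * (crossovers observed on it) / n_progeny`` centimorgans — each
crossover in a haploid product is one recombination event per meiosis.
Crossover point estimates for spacing and proximal/distal statistics use
the midpoint of the flanking-variant interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .layout import GenomeLayout

__all__ = ["GeneticMap", "SpacingStats", "GCBiasFit", "genetic_map",
           "proximal_distal", "spacing", "interval_gc", "fit_gc_bias",
           "loess_smooth"]


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    per_chrom_cm: dict[str, float]
    n_progeny: int

    @property
    def total_morgans(self) -> float:
        return sum(self.per_chrom_cm.values()) / 100.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": list(self.per_chrom_cm),
            "cM": list(self.per_chrom_cm.values()),
            "n_progeny": self.n_progeny,
        })


def genetic_map(events: pd.DataFrame, n_progeny: int,
                layout: GenomeLayout) -> GeneticMap:
    """Per-chromosome map size in cM from pooled crossover events."""
    if n_progeny < 1:
        raise ValueError("n_progeny must be >= 1")
    counts = events.groupby("chrom").size() if len(events) else pd.Series(dtype=int)
    per_chrom = {chrom: 100.0 * counts.get(chrom, 0) / n_progeny
                 for chrom, _ in layout.chromosomes}
    return GeneticMap(per_chrom_cm=per_chrom, n_progeny=n_progeny)


# ---------------------------------------------------------------------------
# centromere-proximal vs distal
# ---------------------------------------------------------------------------

def proximal_distal(events: pd.DataFrame, layout: GenomeLayout) -> pd.DataFrame:
    """Crossover counts in the centromere-proximal vs distal chromosome half.

    Centromeres sit at coordinate 0; an event is proximal when its interval
    midpoint is strictly below half the chromosome length (a midpoint
    exactly at L/2 counts distal).  A two-sided binomial test against
    p=0.5 is reported per chromosome.
    """
    lengths = dict(layout.chromosomes)
    rows = []
    for chrom, length in layout.chromosomes:
        sub = events[events["chrom"] == chrom]
        mid = sub["midpoint"].to_numpy() if len(sub) else np.array([])
        n_prox = int((mid < length / 2).sum())
        n_dist = len(mid) - n_prox
        n = n_prox + n_dist
        pval = float(stats.binomtest(n_prox, n, 0.5).pvalue) if n else float("nan")
        rows.append({"chrom": chrom, "n_proximal": n_prox, "n_distal": n_dist,
                     "proximal_excess": n_prox > n_dist, "p_binomial": pval})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# crossover spacing
# ---------------------------------------------------------------------------

@dataclass
class SpacingStats:
    distances: np.ndarray                 # bp between consecutive midpoints
    close_pair_threshold: int = 50_000

    @property
    def n_close_pairs(self) -> int:
        return int((self.distances < self.close_pair_threshold).sum())

    @property
    def close_pair_fraction(self) -> float:
        return self.n_close_pairs / len(self.distances) if len(self.distances) else float("nan")

    def modal_band(self, lo: int = 100_000, hi: int = 2_000_000,
                   n_bins: int = 19) -> tuple[float, float]:
        """Most populated distance band on a log grid (descriptive summary)."""
        d = self.distances[(self.distances >= lo) & (self.distances <= hi)]
        if len(d) == 0:
            return (float("nan"), float("nan"))
        edges = np.geomspace(lo, hi, n_bins + 1)
        hist, _ = np.histogram(d, bins=edges)
        k = int(hist.argmax())
        return (float(edges[k]), float(edges[k + 1]))


def spacing(events: pd.DataFrame,
            close_pair_threshold: int = 50_000) -> SpacingStats:
    """Distances between consecutive crossover midpoints, per
    progeny-chromosome; chromosomes with < 2 events contribute none."""
    dists = []
    for (_, _), sub in events.groupby(["progeny", "chrom"], sort=False):
        mids = np.sort(sub["midpoint"].to_numpy())
        if len(mids) >= 2:
            dists.append(np.diff(mids))
    d = np.concatenate(dists) if dists else np.array([])
    return SpacingStats(distances=d, close_pair_threshold=close_pair_threshold)


# ---------------------------------------------------------------------------
# interval G+C
# ---------------------------------------------------------------------------

def interval_gc(events: pd.DataFrame,
                reference: dict[str, bytes]) -> pd.DataFrame:
    """G+C fraction of the sequence strictly between the flanking variants.

    The flank bases themselves are excluded — the crossover lies in the
    open interval (left, right) — and ambiguous bases (N) are excluded from
    both numerator and denominator.  Events whose interval is empty after
    exclusions get NaN and ``gc_undefined=True``.
    """
    gc = np.full(len(events), np.nan)
    undef = np.zeros(len(events), dtype=bool)
    for i, (_, ev) in enumerate(events.iterrows()):
        seq = reference[ev["chrom"]][int(ev["left"]) + 1:int(ev["right"])]
        n_gc = seq.count(b"G") + seq.count(b"C") + seq.count(b"g") + seq.count(b"c")
        n_valid = len(seq) - seq.count(b"N") - seq.count(b"n")
        if n_valid == 0:
            undef[i] = True
        else:
            gc[i] = n_gc / n_valid
    out = events.copy()
    out["gc_fraction"] = gc
    out["gc_undefined"] = undef
    return out


# ---------------------------------------------------------------------------
# G+C bias fit
# ---------------------------------------------------------------------------

def loess_smooth(x: np.ndarray, y: np.ndarray, span: float = 0.75,
                 degree: int = 2, x_eval: np.ndarray | None = None,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Local polynomial (Loess) smooth with tricube weights.

    At each evaluation point the nearest ``span`` fraction of the data is
    fit by weighted least squares of the given degree.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    if x_eval is None:
        x_eval = np.linspace(x.min(), x.max(), 100)
    k = max(degree + 1, int(np.ceil(span * len(x))))
    out = np.empty(len(x_eval))
    for i, x0 in enumerate(x_eval):
        d = np.abs(x - x0)
        idx = np.argpartition(d, min(k, len(x)) - 1)[:k]
        dmax = d[idx].max()
        w = (1 - (d[idx] / dmax) ** 3) ** 3 if dmax > 0 else np.ones(k)
        coef = np.polynomial.polynomial.polyfit(
            x[idx] - x0, y[idx], deg=degree, w=np.sqrt(np.maximum(w, 1e-12)))
        out[i] = coef[0]
    return np.asarray(x_eval, float), out


@dataclass
class GCBiasFit:
    """Results of the crossover-interval G+C bias analysis.

    The linear model is fit only on intervals shorter than ``len_cutoff``;
    its y-intercept estimates the G+C composition at true crossover points
    (longer intervals merely approach the genomic average).  The quadratic
    Loess curve uses all intervals.
    """

    slope: float
    intercept: float
    slope_ci99: tuple[float, float]
    intercept_ci99: tuple[float, float]
    len_cutoff: int
    n_fit: int
    loess_x: np.ndarray = field(repr=False)
    loess_y: np.ndarray = field(repr=False)
    skipped: bool = False

    @property
    def y_intercept_estimate(self) -> float:
        return self.intercept

    def summary(self) -> str:
        if self.skipped:
            return "G+C bias fit skipped: insufficient short intervals"
        return (
            f"linear fit on {self.n_fit} intervals < {self.len_cutoff} bp: "
            f"gc = {self.intercept:.4f} + {self.slope:.3e} * len; "
            f"99% CI slope ({self.slope_ci99[0]:.3e}, {self.slope_ci99[1]:.3e}),"
            f" intercept ({self.intercept_ci99[0]:.4f}, "
            f"{self.intercept_ci99[1]:.4f})"
        )


def fit_gc_bias(events: pd.DataFrame, len_cutoff: int = 300,
                span: float = 0.75) -> GCBiasFit:
    """OLS of interval G+C on interval length (< cutoff) + quadratic Loess.

    Requires >= 3 events below the cutoff for the linear fit; otherwise the
    fit is flagged ``skipped`` with NaN estimates.
    """
    import statsmodels.api as sm

    ev = events.dropna(subset=["gc_fraction"])
    short = ev[ev["interval_len"] < len_cutoff]
    lx, ly = (np.array([]), np.array([]))
    if len(ev) >= 3:
        lx, ly = loess_smooth(ev["interval_len"].to_numpy(),
                              ev["gc_fraction"].to_numpy(), span=span)
    if len(short) < 3:
        return GCBiasFit(slope=float("nan"), intercept=float("nan"),
                         slope_ci99=(float("nan"), float("nan")),
                         intercept_ci99=(float("nan"), float("nan")),
                         len_cutoff=len_cutoff, n_fit=len(short),
                         loess_x=lx, loess_y=ly, skipped=True)
    X = sm.add_constant(short["interval_len"].to_numpy(dtype=float))
    res = sm.OLS(short["gc_fraction"].to_numpy(), X).fit()
    ci = res.conf_int(alpha=0.01)
    return GCBiasFit(
        slope=float(res.params[1]), intercept=float(res.params[0]),
        slope_ci99=(float(ci[1][0]), float(ci[1][1])),
        intercept_ci99=(float(ci[0][0]), float(ci[0][1])),
        len_cutoff=len_cutoff, n_fit=len(short), loess_x=lx, loess_y=ly)
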