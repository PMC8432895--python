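"""Synteny-decay regression with permutational F-tests.

The question: how does pairwise gene-order conservation (GOC) decay with
phylogenetic distance, and do taxonomic orders decay at different rates?
Observations are within-order taxon pairs (order, d, y) where d is the
patristic distance on a unit-height tree and y the pairwise GOC score.
Three decay forms are fitted by ordinary least squares on a transformed
response:

* linear:       y = a + b·d
* exponential:  log y = a + b·d          (y = e^a · e^{b d})
* power law:    log y = a + b·log d      (y = e^a · d^b)

With ``by_order`` grouping each order gets its own intercept and slope
(cell-means coding; 2m parameters for m orders). The model F statistic
compares the fit to the intercept-only model on the same response scale:
F = (ESS/df_model)/(RSS/df_resid) with df_model = 2m − 1 and
df_resid = n − 2m.

Because pairwise distances are not independent observations, significance
is assessed permutationally: each permutation applies one uniform random
permutation of the taxon labels of the GOC matrix (values reindexed as
G[π(i), π(j)]) while the distance matrix and the order classification stay
fixed; the pair dataset is rebuilt and F recomputed. The p-value is the
add-one estimator (1 + #{F_null ≥ F_obs}) / (1 + n_perm). Model choice is
by the highest model F (not information criteria, which behave poorly for
distance-matrix regressions); note the F values of the three forms live on
different response scales (raw y vs log y), which is inherent to this
comparison rule and flagged in the report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phylo_distance import normalize_taxon

__all__ = [
    "build_pair_dataset",
    "subset_excluding",
    "SyntenyDecayModel",
    "DecayFitResults",
    "PermutationResult",
    "compare_models",
    "read_order_map",
]

FORMS = ("linear", "exponential", "power")


def read_order_map(path) -> dict[str, str]:
    """Two-column TSV (taxon, order) -> normalized-label dict."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1])
    return {normalize_taxon(t): str(o) for t, o in zip(df[0], df[1])}


# ---------------------------------------------------------------------------
# pair dataset

def build_pair_dataset(
    goc: pd.DataFrame,
    dist: pd.DataFrame,
    orders: Mapping[str, str],
    min_taxa_per_order: int = 4,
) -> pd.DataFrame:
    """Within-order pair observations (taxon_a, taxon_b, order, d, y).

    ``goc`` and ``dist`` are square labeled matrices over the same taxa
    (label matching is exact after space/underscore normalization). One
    observation per unordered pair of distinct taxa sharing an order; orders
    with fewer than ``min_taxa_per_order`` taxa are dropped with a warning.
    """
    goc = goc.copy()
    goc.index = [normalize_taxon(x) for x in goc.index]
    goc.columns = [normalize_taxon(x) for x in goc.columns]
    dist = dist.copy()
    dist.index = [normalize_taxon(x) for x in dist.index]
    dist.columns = [normalize_taxon(x) for x in dist.columns]

    only_goc = sorted(set(goc.index) - set(dist.index))
    only_dist = sorted(set(dist.index) - set(goc.index))
    if only_goc or only_dist:
        raise ValueError(
            "taxon sets differ between GOC and distance matrices; "
            f"only in GOC: {only_goc[:5]}; only in distances: {only_dist[:5]}"
        )
    taxa = list(goc.index)
    missing = sorted(set(taxa) - {normalize_taxon(t) for t in orders})
    if missing:
        raise ValueError(f"taxa without an order classification: {missing[:5]}")
    omap = {normalize_taxon(t): o for t, o in orders.items()}

    counts = pd.Series([omap[t] for t in taxa]).value_counts()
    kept_orders = set(counts[counts >= min_taxa_per_order].index)
    dropped = sorted(set(counts.index) - kept_orders)
    if dropped:
        warnings.warn(
            f"orders below min_taxa_per_order={min_taxa_per_order} dropped: "
            f"{dropped}",
            stacklevel=2,
        )

    dist = dist.loc[taxa, taxa]
    rows = []
    for i, ta in enumerate(taxa):
        for j in range(i + 1, len(taxa)):
            tb = taxa[j]
            if omap[ta] != omap[tb] or omap[ta] not in kept_orders:
                continue
            rows.append(
                (ta, tb, omap[ta], float(dist.iat[i, j]), float(goc.iat[i, j]))
            )
    return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "order", "d", "y"])


def subset_excluding(pairs: pd.DataFrame, order_name: str) -> pd.DataFrame:
    """All pair observations except those of ``order_name``."""
    if order_name not in set(pairs["order"]):
        raise KeyError(f"order {order_name!r} not present in the pair dataset")
    return pairs[pairs["order"] != order_name].reset_index(drop=True)


# ---------------------------------------------------------------------------
# transforms and closed-form grouped OLS

def _transform(form: str, d: np.ndarray, y: np.ndarray):
    """(x, z, keep_mask) for the form's response scale."""
    if form == "linear":
        return d, y, np.ones(len(y), dtype=bool)
    if form == "exponential":
        keep = y > 0
        return d, np.log(np.where(keep, y, 1.0)), keep
    if form == "power":
        keep = (y > 0) & (d > 0)
        return np.log(np.where(d > 0, d, 1.0)), np.log(np.where(keep, y, 1.0)), keep
    raise ValueError(f"unknown form {form!r}; expected one of {FORMS}")


def _group_stats(x, z, codes, m):
    """Per-group centered sums for simple OLS, via one pass of bincounts."""
    cnt = np.bincount(codes, minlength=m).astype(float)
    sx = np.bincount(codes, weights=x, minlength=m)
    sz = np.bincount(codes, weights=z, minlength=m)
    sxx = np.bincount(codes, weights=x * x, minlength=m)
    sxz = np.bincount(codes, weights=x * z, minlength=m)
    szz = np.bincount(codes, weights=z * z, minlength=m)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx, mz = sx / cnt, sz / cnt
        cxx = sxx - cnt * mx * mx
        cxz = sxz - cnt * mx * mz
        czz = szz - cnt * mz * mz
    return cnt, mx, mz, cxx, cxz, czz


def _fit_groups(x, z, codes, m):
    """Separate intercept+slope per group; returns (intercepts, slopes,
    rss_full, rss_reduced, slope_common)."""
    cnt, mx, mz, cxx, cxz, czz = _group_stats(x, z, codes, m)
    if np.any(cnt < 3):
        raise ValueError("a group has fewer than 3 observations")
    if np.any(cxx <= 0):
        raise ValueError("a group has no variation in distance")
    slopes = cxz / cxx
    intercepts = mz - slopes * mx
    rss_full = float(np.sum(czz - cxz * cxz / cxx))
    slope_common = float(cxz.sum() / cxx.sum())
    rss_red = float(
        np.sum(czz - 2 * slope_common * cxz + slope_common**2 * cxx)
    )
    return intercepts, slopes, max(rss_full, 0.0), max(rss_red, 0.0), slope_common


def _model_f(z, rss, n_params):
    n = len(z)
    tss = float(np.sum((z - z.mean()) ** 2))
    ess = max(tss - rss, 0.0)
    df_model = n_params - 1
    df_resid = n - n_params
    if df_resid <= 0:
        raise ValueError("not enough observations for the model")
    f = np.inf if rss == 0 else (ess / df_model) / (rss / df_resid)
    return f, ess, tss, df_model, df_resid


# ---------------------------------------------------------------------------
# results containers

@dataclass
class PermutationResult:
    """Outcome of a permutational F-test."""

    F_obs: float
    null_F: np.ndarray
    n_perm: int
    p: float
    seed: int | None
    df: tuple[int, int]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"PermutationResult(F={self.F_obs:.4g}, df={self.df}, "
            f"p={self.p:.4g}, n_perm={self.n_perm})"
        )


@dataclass
class DecayFitResults:
    """Least-squares fit of one decay form.

    ``params`` holds intercept and slope per order (index = order name, or
    ``"common"``) on the model's response scale: for the exponential form
    the fitted curve is ``y = exp(intercept) * exp(slope * d)``, for the
    power law ``y = exp(intercept) * d**slope``.
    """

    model: "SyntenyDecayModel"
    form: str
    grouping: str
    params: pd.DataFrame
    rss: float
    ess: float
    tss: float
    df_model: int
    df_resid: int
    F: float
    n: int
    n_dropped: int
    rss_common_slope: float | None = None

    @property
    def fvalue(self) -> float:
        return self.F

    def predict(self, d: np.ndarray, order: str | None = None) -> np.ndarray:
        """Fitted y on the original scale."""
        key = order if self.grouping == "by_order" else "common"
        a = float(self.params.loc[key, "intercept"])
        b = float(self.params.loc[key, "slope"])
        d = np.asarray(d, dtype=float)
        if self.form == "linear":
            return a + b * d
        if self.form == "exponential":
            return np.exp(a + b * d)
        return np.exp(a) * d**b

    def summary(self) -> str:
        lines = [
            "Synteny decay model".center(60),
            "=" * 60,
            f"form: {self.form:<14} grouping: {self.grouping}",
            f"n obs: {self.n:<12} dropped (nonpositive under log): {self.n_dropped}",
            f"F({self.df_model}, {self.df_resid}) = {self.F:.6g}",
            f"RSS = {self.rss:.6g}   ESS = {self.ess:.6g}   TSS = {self.tss:.6g}",
            "-" * 60,
            f"{'group':<20}{'intercept':>14}{'slope':>14}",
        ]
        for name, row in self.params.iterrows():
            lines.append(f"{name:<20}{row['intercept']:>14.6g}{row['slope']:>14.6g}")
        lines.append("=" * 60)
        if self.form != "linear":
            lines.append("coefficients are on the log-response scale")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# the model

class SyntenyDecayModel:
    """Least-squares decay model over within-order pair observations.

    Construct from a tidy pair table, or with :meth:`from_matrices` from a
    GOC matrix, a distance matrix and a taxon→order classification — the
    matrix route also enables the permutation tests, whose unit of
    permutation is the taxon labeling of the GOC matrix.

    Parameters
    ----------
    pairs
        DataFrame with columns order, d, y (taxon_a/taxon_b optional).
    form
        "linear", "exponential" or "power".
    grouping
        "by_order" (per-order intercept and slope) or "common".
    """

    def __init__(
        self,
        pairs: pd.DataFrame,
        form: str = "exponential",
        grouping: str = "by_order",
        *,
        nonpositive: str = "drop",
    ) -> None:
        if form not in FORMS:
            raise ValueError(f"form must be one of {FORMS}")
        if grouping not in {"by_order", "common"}:
            raise ValueError("grouping must be 'by_order' or 'common'")
        required = {"order", "d", "y"}
        if not required <= set(pairs.columns):
            raise ValueError(f"pairs must have columns {sorted(required)}")
        if (pairs["d"] <= 0).any() and form == "power":
            pass  # handled by the transform's keep mask
        self.pairs = pairs.reset_index(drop=True)
        self.form = form
        self.grouping = grouping
        self.nonpositive = nonpositive
        # matrix context (set by from_matrices) for permutation tests
        self._G: np.ndarray | None = None
        self._pair_idx: tuple[np.ndarray, np.ndarray] | None = None
        self._d_vec: np.ndarray | None = None
        self._codes: np.ndarray | None = None
        self._m: int | None = None

    # -- construction ------------------------------------------------------

    @classmethod
    def from_matrices(
        cls,
        goc: pd.DataFrame,
        dist: pd.DataFrame,
        orders: Mapping[str, str],
        form: str = "exponential",
        grouping: str = "by_order",
        *,
        min_taxa_per_order: int = 4,
        nonpositive: str = "drop",
    ) -> "SyntenyDecayModel":
        pairs = build_pair_dataset(goc, dist, orders, min_taxa_per_order)
        model = cls(pairs, form=form, grouping=grouping, nonpositive=nonpositive)
        taxa = [normalize_taxon(t) for t in goc.index]
        tpos = {t: i for i, t in enumerate(taxa)}
        model._G = np.asarray(goc.values, dtype=float)
        ia = pairs["taxon_a"].map(tpos).to_numpy()
        ib = pairs["taxon_b"].map(tpos).to_numpy()
        model._pair_idx = (ia, ib)
        model._d_vec = pairs["d"].to_numpy(dtype=float)
        order_names = sorted(pairs["order"].unique())
        codes = pairs["order"].map({o: i for i, o in enumerate(order_names)})
        model._codes = codes.to_numpy(dtype=np.int64)
        model._m = len(order_names)
        model._order_names = order_names
        return model

    # -- fitting -----------------------------------------------------------

    def _prepared(self, y: np.ndarray | None = None):
        d = self.pairs["d"].to_numpy(dtype=float)
        if y is None:
            y = self.pairs["y"].to_numpy(dtype=float)
        x, z, keep = _transform(self.form, d, y)
        n_dropped = int((~keep).sum())
        if n_dropped and self.nonpositive == "drop":
            frac = n_dropped / len(y)
            if frac > 0.01:
                raise ValueError(
                    f"{n_dropped} observations ({frac:.1%}) nonpositive under "
                    f"the {self.form} model; pass nonpositive='force' to "
                    "proceed anyway"
                )
        return x[keep], z[keep], keep, n_dropped

    def fit(self) -> DecayFitResults:
        """Ordinary least squares on the form's response scale; the F
        statistic compares against the intercept-only model on that scale."""
        x, z, keep, n_dropped = self._prepared()
        if self.grouping == "by_order":
            order_names = sorted(self.pairs["order"].unique())
            omap = {o: i for i, o in enumerate(order_names)}
            codes = self.pairs["order"].map(omap).to_numpy(dtype=np.int64)[keep]
            m = len(order_names)
            a, b, rss, rss_red, _ = _fit_groups(x, z, codes, m)
            params = pd.DataFrame(
                {"intercept": a, "slope": b}, index=pd.Index(order_names, name="order")
            )
            n_params = 2 * m
        else:
            codes = np.zeros(len(x), dtype=np.int64)
            a, b, rss, rss_red, _ = _fit_groups(x, z, codes, 1)
            params = pd.DataFrame(
                {"intercept": a, "slope": b}, index=pd.Index(["common"])
            )
            n_params = 2
        f, ess, tss, df_model, df_resid = _model_f(z, rss, n_params)
        return DecayFitResults(
            model=self,
            form=self.form,
            grouping=self.grouping,
            params=params,
            rss=rss,
            ess=ess,
            tss=tss,
            df_model=df_model,
            df_resid=df_resid,
            F=f,
            n=len(z),
            n_dropped=n_dropped,
            rss_common_slope=rss_red,
        )

    # -- permutation machinery --------------------------------------------

    def _require_matrices(self):
        if self._G is None:
            raise ValueError(
                "permutation tests need the matrix context; build the model "
                "with SyntenyDecayModel.from_matrices(...)"
            )

    def _stat_model_f(self, y: np.ndarray) -> float:
        x, z, keep = _transform(self.form, self._d_vec, y)
        x, z = x[keep], z[keep]
        codes = self._codes[keep]
        m = self._m if self.grouping == "by_order" else 1
        if self.grouping != "by_order":
            codes = np.zeros(len(x), dtype=np.int64)
        try:
            _, _, rss, _, _ = _fit_groups(x, z, codes, m)
            f, *_ = _model_f(z, rss, 2 * m)
        except ValueError:
            return np.nan
        return f

    def _stat_interaction_f(self, y: np.ndarray) -> float:
        x, z, keep = _transform(self.form, self._d_vec, y)
        x, z = x[keep], z[keep]
        codes = self._codes[keep]
        m = self._m
        try:
            _, _, rss_full, rss_red, _ = _fit_groups(x, z, codes, m)
        except ValueError:
            return np.nan
        q = m - 1
        df_full = len(z) - 2 * m
        if df_full <= 0 or rss_full == 0:
            return np.inf
        return ((rss_red - rss_full) / q) / (rss_full / df_full)

    def _permute(self, stat, n_perm: int, seed: int | None) -> PermutationResult:
        self._require_matrices()
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        ia, ib = self._pair_idx
        y_obs = self.pairs["y"].to_numpy(dtype=float)
        f_obs = stat(y_obs)
        n_taxa = self._G.shape[0]
        null = np.empty(n_perm)
        for b in range(n_perm):
            pi = rng.permutation(n_taxa)
            null[b] = stat(self._G[pi[ia], pi[ib]])
        valid = ~np.isnan(null)
        exceed = int(np.sum(null[valid] >= f_obs))
        p = (1 + exceed) / (1 + int(valid.sum()))
        return PermutationResult(
            F_obs=f_obs,
            null_F=null,
            n_perm=n_perm,
            p=p,
            seed=seed,
            df=self._df_for(stat),
        )

    def _df_for(self, stat) -> tuple[int, int]:
        x, z, keep, _ = self._prepared()
        m = self._m if self.grouping == "by_order" else 1
        if stat == self._stat_interaction_f:
            return (m - 1, len(z) - 2 * m)
        return (2 * m - 1, len(z) - 2 * m)

    def permutation_test(
        self, n_perm: int = 4999, seed: int | None = None
    ) -> PermutationResult:
        """Permutational significance of the whole-model F: taxon labels of
        the GOC matrix are permuted globally; distances and the order
        classification stay fixed."""
        return self._permute(self._stat_model_f, n_perm, seed)

    def interaction_test(
        self, n_perm: int = 4999, seed: int | None = None
    ) -> PermutationResult:
        """Do orders differ in decay rate? Nested-model F of order-specific
        slopes (full) against a common slope with order intercepts
        (reduced), assessed by the same taxon-label permutation."""
        self._require_matrices()
        if self.grouping != "by_order" or self._m < 2:
            raise ValueError("interaction test needs by_order grouping with >= 2 orders")
        return self._permute(self._stat_interaction_f, n_perm, seed)


# ---------------------------------------------------------------------------
# model comparison

def compare_models(
    goc: pd.DataFrame,
    dist: pd.DataFrame,
    orders: Mapping[str, str],
    n_perm: int = 4999,
    seed: int | None = None,
    *,
    min_taxa_per_order: int = 4,
    forms: Sequence[str] = FORMS,
) -> pd.DataFrame:
    """Fit all decay forms with by-order grouping and rank them by model F
    (the comparison criterion here — not AIC/BIC, which are unreliable for
    distance-matrix regressions).

    Returns a frame with one row per form: F, df, permutational p, n,
    dropped count, rank. Note each F lives on its own response scale (raw y
    for linear, log y otherwise); the ranking rule accepts that.
    """
    rows = []
    for form in forms:
        model = SyntenyDecayModel.from_matrices(
            goc, dist, orders, form=form, min_taxa_per_order=min_taxa_per_order
        )
        res = model.fit()
        perm = model.permutation_test(n_perm=n_perm, seed=seed)
        rows.append(
            {
                "form": form,
                "F": res.F,
                "df_model": res.df_model,
                "df_resid": res.df_resid,
                "p_perm": perm.p,
                "n": res.n,
                "n_dropped": res.n_dropped,
            }
        )
    report = pd.DataFrame(rows).sort_values("F", ascending=False).reset_index(drop=True)
    report["rank"] = np.arange(1, len(report) + 1)
    return report
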