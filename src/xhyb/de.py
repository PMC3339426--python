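"""Two-color microarray differential-expression statistics.

The chain mirrors the standard two-channel cDNA-array analysis:

1. spots flagged bad by the scanner get weight 0 (kept, not deleted);
2. per-channel normexp background correction (normal noise + exponential
   signal convolution, parameters fitted by maximum likelihood per array
   per channel) plus an offset to keep intensities strictly positive;
3. M/A transform with dye-swap orientation folded into the sign of M;
4. print-tip loess normalization of M on A within each print-tip group;
5. a consensus correlation for within-array duplicate spots;
6. per-probe generalized least squares of M on the array design, treating
   duplicate spots as correlated observations;
7. empirical-Bayes moderation of the residual variances (variances
   shrunk toward a pooled prior fitted by matching moments of log s^2 to
   a scaled-F model), giving moderated t-statistics with augmented
   degrees of freedom;
8. Benjamini-Hochberg FDR adjustment and a two-line direction
   classification of jointly significant probes.

:class:`TwoColorDEModel` bundles the chain; its :meth:`~TwoColorDEModel.fit`
returns a :class:`DEResults` carrying the per-probe table, the fitted
hyperparameters and the classification helpers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from xhyb.io import TwoColorArray

logger = logging.getLogger(__name__)

MIN_SPOTS_PER_TIP_GROUP = 10
MIN_DUPLICATE_PROBES = 5
RHO_CLAMP = 0.99


@dataclass
class NormalizationParams:
    """Tunables of the pre-statistics chain.

    normexp_offset : intensity units added after background correction so
        corrected intensities stay strictly positive (default 50).
    loess_span : fraction of spots in each local regression window.
    loess_iterations : robustness (bisquare) iterations.
    """
    normexp_offset: float = 50.0
    loess_span: float = 0.3
    loess_iterations: int = 4

    def __post_init__(self):
        if self.normexp_offset < 0:
            raise ValueError("normexp_offset must be >= 0")
        if not 0 < self.loess_span <= 1:
            raise ValueError("loess_span must be in (0, 1]")


@dataclass
class MAData:
    """Per-spot M (log2 ratio) and A (mean log2 intensity) of one array."""
    data: pd.DataFrame  # columns: probe_id, block, M, A, weight
    array_id: str

    def __len__(self):
        return len(self.data)


# ---------------------------------------------------------------------------
# 1. flag filtering

def flag_filter(array: TwoColorArray) -> np.ndarray:
    """Per-spot weights: 0 for negative (GenePix "bad") flags, else 1."""
    return (array.spots["flag"].to_numpy() >= 0).astype(float)


# ---------------------------------------------------------------------------
# 2. normexp background correction

def _normexp_negloglik(theta: np.ndarray, x: np.ndarray) -> float:
    mu, logsigma, logalpha = theta
    sigma, alpha = np.exp(logsigma), np.exp(logalpha)
    z = (x - mu - sigma**2 / alpha) / sigma
    ll = (-np.log(alpha) + (mu - x) / alpha + sigma**2 / (2 * alpha**2)
          + stats.norm.logcdf(z))
    return -np.sum(ll)


def normexp_fit(x: np.ndarray) -> tuple[float, float, float]:
    """Maximum-likelihood fit of the normexp convolution to fg - bg values.

    The observed net intensity is modeled as B + S with background
    B ~ N(mu, sigma^2) and true signal S ~ Exp(alpha).  Returns
    (mu, sigma, alpha).
    """
    x = np.asarray(x, dtype=float)
    spread = np.std(x)
    if spread == 0 or len(x) < 4:
        raise ValueError("degenerate input: constant or too-short vector")
    lower = x[x < np.quantile(x, 0.25)]
    sigma0 = max(np.std(lower) if len(lower) > 1 else spread / 10,
                 spread / 100, 1e-6)
    mu0 = float(np.quantile(x, 0.05))
    alpha0 = max(float(np.mean(x) - mu0), sigma0)
    best = None
    for start in ([mu0, np.log(sigma0), np.log(alpha0)],
                  [np.median(x) - spread, np.log(spread / 2),
                   np.log(max(spread, 1e-3))]):
        res = optimize.minimize(_normexp_negloglik, start, args=(x,),
                                method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10,
                                         "maxiter": 5000})
        if best is None or res.fun < best.fun:
            best = res
    mu, logsigma, logalpha = best.x
    return float(mu), float(np.exp(logsigma)), float(np.exp(logalpha))


def normexp_signal(params: tuple[float, float, float],
                   x: np.ndarray) -> np.ndarray:
    """Posterior expected true signal E[S | B + S = x]; strictly positive."""
    mu, sigma, alpha = params
    mu_sf = np.asarray(x, dtype=float) - mu - sigma**2 / alpha
    z = mu_sf / sigma
    # phi(z)/Phi(z) via the scaled complementary error function, stable
    # for arbitrarily negative z
    mills_ratio = np.sqrt(2 / np.pi) / special.erfcx(-z / np.sqrt(2))
    signal = mu_sf + sigma * mills_ratio
    return np.maximum(signal, np.finfo(float).tiny)


def normexp_background(array: TwoColorArray,
                       offset: float = 50.0) -> pd.DataFrame:
    """normexp-corrected intensities per channel, plus the offset.

    Returns a DataFrame with columns ``ch1`` and ``ch2`` of strictly
    positive corrected intensities.  On degenerate input (constant net
    intensity) the correction falls back to a floored subtraction with a
    warning.
    """
    out = {}
    for ch in ("ch1", "ch2"):
        net = (array.spots[f"fg_{ch}"] - array.spots[f"bg_{ch}"]).to_numpy()
        try:
            params = normexp_fit(net)
            signal = normexp_signal(params, net)
        except ValueError:
            warnings.warn(
                f"array {array.array_id} channel {ch}: degenerate "
                "intensities, falling back to floored subtraction")
            signal = np.maximum(net - net.min(), 0.0)
        out[ch] = signal + offset
    return pd.DataFrame(out, index=array.spots.index)


# ---------------------------------------------------------------------------
# 3. M/A transform

def compute_MA(array: TwoColorArray, corrected: pd.DataFrame,
               weights: np.ndarray | None = None) -> MAData:
    """M/A values with the dye-swap orientation folded into M's sign.

    M = log2(treatment / reference); A = mean log2 intensity.  Which
    physical channel is "treatment" comes from ``array.dye_orientation``,
    so dye-swapped slides end up on a common sign convention here and the
    downstream design matrix needs no swap column.
    """
    l1 = np.log2(corrected["ch1"].to_numpy())
    l2 = np.log2(corrected["ch2"].to_numpy())
    if array.dye_orientation == "treatment_in_ch1":
        m = l1 - l2
    else:
        m = l2 - l1
    a = 0.5 * (l1 + l2)
    if weights is None:
        weights = flag_filter(array)
    df = pd.DataFrame({
        "probe_id": array.spots["probe_id"].to_numpy(),
        "block": array.spots["block"].to_numpy(),
        "M": m, "A": a, "weight": weights})
    return MAData(df, array.array_id)


# ---------------------------------------------------------------------------
# 4. print-tip loess

def printtip_loess(ma: MAData, span: float = 0.3,
                   iterations: int = 4) -> MAData:
    """Print-tip loess normalization: M <- M - loess(M ~ A) per block.

    Weight-0 spots are excluded from fitting but still normalized.  A
    print-tip group with fewer than :data:`MIN_SPOTS_PER_TIP_GROUP`
    usable spots falls back to the whole-array (global) loess fit, with
    a warning.
    """
    df = ma.data.copy()
    usable_all = (df["weight"] > 0) & np.isfinite(df["M"]) & np.isfinite(df["A"])

    def fit_predict(fit_idx, predict_idx):
        a_fit = df.loc[fit_idx, "A"].to_numpy()
        m_fit = df.loc[fit_idx, "M"].to_numpy()
        curve = lowess(m_fit, a_fit, frac=span, it=iterations,
                       return_sorted=True)
        a_pred = df.loc[predict_idx, "A"].to_numpy()
        return np.interp(a_pred, curve[:, 0], curve[:, 1])

    trend = np.full(len(df), np.nan)
    global_needed = []
    for block, group in df.groupby("block"):
        fit_idx = group.index[usable_all.loc[group.index]]
        if len(fit_idx) < MIN_SPOTS_PER_TIP_GROUP:
            global_needed.append(block)
            continue
        trend[df.index.get_indexer(group.index)] = fit_predict(
            fit_idx, group.index)
    if global_needed:
        warnings.warn(
            f"array {ma.array_id}: print-tip group(s) {global_needed} have "
            f"< {MIN_SPOTS_PER_TIP_GROUP} usable spots; using global loess")
        fit_idx = df.index[usable_all]
        mask = df["block"].isin(global_needed)
        trend[mask.to_numpy()] = fit_predict(fit_idx, df.index[mask])
    df["M"] = df["M"] - trend
    return MAData(df, ma.array_id)


# ---------------------------------------------------------------------------
# 5. duplicate correlation

def find_duplicates(mas: list[MAData]) -> list[str]:
    """Probes printed exactly twice on every array."""
    common = None
    for ma in mas:
        counts = ma.data["probe_id"].value_counts()
        twos = set(counts[counts == 2].index)
        common = twos if common is None else common & twos
    return sorted(common or ())


def duplicate_correlation(mas: list[MAData],
                          duplicate_probes: list[str] | None = None
                          ) -> float:
    """Consensus within-array correlation of duplicate spots.

    Per probe, the M-values of its first and second spot are paired
    across arrays and their Pearson correlation computed; the per-probe
    correlations are Fisher-z transformed, bias-corrected for the small
    number of arrays, robustly averaged (trimmed mean, 15 % each tail)
    and back-transformed.  The consensus is clamped to
    (-:data:`RHO_CLAMP`, :data:`RHO_CLAMP`).

    This is a deterministic trimmed Fisher-z consensus, not the REML
    mixed-model estimator used by some packages; the difference is noted
    in the fit metadata.
    """
    if duplicate_probes is None:
        duplicate_probes = find_duplicates(mas)
    n_arrays = len(mas)
    per_array = []
    for ma in mas:
        dup = ma.data[ma.data["probe_id"].isin(duplicate_probes)
                      & (ma.data["weight"] > 0)]
        dup = dup.sort_values(["probe_id", "block"], kind="stable")
        first = dup.drop_duplicates("probe_id", keep="first").set_index(
            "probe_id")["M"]
        rest = dup[dup.duplicated("probe_id", keep="first")]
        second = rest.drop_duplicates("probe_id", keep="first").set_index(
            "probe_id")["M"]
        per_array.append((first, second))
    zs = []
    for probe in duplicate_probes:
        m1 = np.array([fa.get(probe, np.nan) for fa, _ in per_array])
        m2 = np.array([sa.get(probe, np.nan) for _, sa in per_array])
        if np.isnan(m1).any() or np.isnan(m2).any():
            continue
        if np.std(m1) == 0 and np.std(m2) == 0 and np.allclose(m1, m2):
            r = 1.0
        elif np.std(m1) == 0 or np.std(m2) == 0:
            continue
        else:
            r = float(np.corrcoef(m1, m2)[0, 1])
        r = np.clip(r, -0.9999, 0.9999)
        # small-sample bias correction: E[z_r] ~ atanh(rho) + rho/(2(n-1))
        zs.append(np.arctanh(r) - r / (2 * (n_arrays - 1)))
    if len(zs) < MIN_DUPLICATE_PROBES:
        raise ValueError(
            f"only {len(zs)} probes with complete duplicate data "
            f"(need >= {MIN_DUPLICATE_PROBES})")
    consensus = float(np.tanh(stats.trim_mean(zs, 0.15)))
    return float(np.clip(consensus, -RHO_CLAMP, RHO_CLAMP))


# ---------------------------------------------------------------------------
# 6. per-probe generalized least squares

def fit_linear_model(mas: list[MAData], design: pd.DataFrame,
                     rho: float = 0.0) -> pd.DataFrame:
    """GLS fit of M on the array design, one fit per probe.

    ``design`` has one row per array (index = array_id) and one column
    per coefficient.  Within-array duplicate spots of the same probe are
    treated as observations with correlation ``rho``.  Returns one row
    per probe with ``coef_<c>``, ``se_unscaled_<c>`` per coefficient plus
    ``sigma`` (residual sd) and ``df`` (residual degrees of freedom).
    Probes with fewer usable observations than estimable coefficients are
    marked unestimable (all-NaN coefficients).
    """
    if not -1 < rho < 1:
        raise ValueError("rho must be in (-1, 1)")
    coef_names = list(design.columns)
    # gather usable observations per probe
    obs: dict[str, list[tuple[int, float]]] = {}
    for ai, ma in enumerate(mas):
        if ma.array_id not in design.index:
            raise KeyError(f"array {ma.array_id} missing from design")
        d = ma.data
        ok = (d["weight"] > 0) & np.isfinite(d["M"])
        for probe, m in zip(d.loc[ok, "probe_id"], d.loc[ok, "M"]):
            obs.setdefault(probe, []).append((ai, float(m)))
    design_rows = design.loc[[ma.array_id for ma in mas]].to_numpy()
    rows = []
    for probe in sorted(obs):
        entries = obs[probe]
        y = np.array([m for _, m in entries])
        X = np.array([design_rows[ai] for ai, _ in entries])
        arrays = np.array([ai for ai, _ in entries])
        n = len(y)
        # block correlation: rho between same-probe spots on the same array
        V = np.eye(n)
        if rho != 0:
            same = arrays[:, None] == arrays[None, :]
            V = np.where(same, rho, 0.0)
            np.fill_diagonal(V, 1.0)
        L = np.linalg.cholesky(V)
        yw = np.linalg.solve(L, y)
        Xw = np.linalg.solve(L, X)
        est = np.flatnonzero(np.any(Xw != 0, axis=0))
        coefs = np.full(len(coef_names), np.nan)
        ses = np.full(len(coef_names), np.nan)
        sigma, dof = np.nan, 0
        if est.size:
            Xe = Xw[:, est]
            rank = np.linalg.matrix_rank(Xe)
            if n >= rank and rank == Xe.shape[1]:
                xtx_inv = np.linalg.inv(Xe.T @ Xe)
                beta = xtx_inv @ Xe.T @ yw
                resid = yw - Xe @ beta
                dof = n - rank
                if dof > 0:
                    sigma = float(np.sqrt(resid @ resid / dof))
                coefs[est] = beta
                ses[est] = np.sqrt(np.diag(xtx_inv))
        row = {"probe_id": probe, "sigma": sigma, "df": dof, "n_obs": n}
        for j, name in enumerate(coef_names):
            row[f"coef_{name}"] = coefs[j]
            row[f"se_unscaled_{name}"] = ses[j]
        rows.append(row)
    return pd.DataFrame(rows).set_index("probe_id")


# ---------------------------------------------------------------------------
# 7. empirical-Bayes moderation

def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Fit s^2 ~ s0^2 * F(df, d0) by matching moments of log s^2.

    Returns (d0, s0_squared); d0 = inf when the log-variances show no
    excess dispersion beyond what their own degrees of freedom explain.
    """
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    if len(s2) < 2:
        raise ValueError("need >= 2 positive variances to fit the prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    emean = e.mean()
    evar = np.var(e, ddof=1) - np.mean(special.polygamma(1, df / 2))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2 * trigamma_inverse(evar)
    s02 = np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2))
    return float(d0), float(s02)


def squeeze_var(s2: np.ndarray, df: np.ndarray,
                d0: float, s02: float) -> np.ndarray:
    """Posterior (moderated) variances s~^2 = (d0 s0^2 + d s^2)/(d0 + d)."""
    s2 = np.where(np.isfinite(s2), s2, 0.0)
    if np.isinf(d0):
        return np.full_like(s2, s02, dtype=float)
    return (d0 * s02 + df * s2) / (d0 + df)


def ebayes_moderate(fit: pd.DataFrame,
                    coef_names: list[str]) -> tuple[pd.DataFrame, dict]:
    """Moderated t-statistics and p-values for every coefficient.

    Hyperparameters (d0, s0^2) come from :func:`fit_f_dist` on the
    ensemble of residual variances; each probe's variance is shrunk
    toward s0^2 and its t-statistic referred to a t distribution with
    d0 + df degrees of freedom (normal in the d0 = inf limit).
    """
    s2 = fit["sigma"].to_numpy() ** 2
    df = fit["df"].to_numpy().astype(float)
    if np.sum(np.isfinite(s2) & (df > 0)) < 50:
        raise ValueError("need >= 50 probes with residual variance to "
                         "estimate the variance prior")
    d0, s02 = fit_f_dist(s2, df)
    s2_post = squeeze_var(s2, df, d0, s02)
    df_total = df + d0
    out = fit.copy()
    out["s2_posterior"] = s2_post
    for name in coef_names:
        t = (out[f"coef_{name}"]
             / (out[f"se_unscaled_{name}"] * np.sqrt(s2_post)))
        if np.isinf(d0):
            p = 2 * stats.norm.sf(np.abs(t))
        else:
            p = 2 * stats.t.sf(np.abs(t), df_total)
        out[f"t_{name}"] = t
        out[f"p_{name}"] = p
    hyper = {"d0": d0, "s0_squared": s02, "n_probes": len(fit)}
    return out, hyper


# ---------------------------------------------------------------------------
# 8. FDR and classification

def fdr_adjust(p: np.ndarray, method: str = "bh") -> np.ndarray:
    """Step-up FDR adjustment (BH, or BY for dependent tests).

    NaN p-values propagate to NaN q-values and are excluded from the
    number of tests m.
    """
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = len(pv)
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order]
    factor = m / np.arange(1, m + 1)
    if method == "by":
        factor = factor * np.sum(1.0 / np.arange(1, m + 1))
    elif method != "bh":
        raise ValueError(f"unknown FDR method {method!r}")
    adj = np.minimum.accumulate((ranked * factor)[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    qv = np.empty(m)
    qv[order] = adj
    q[ok] = qv
    return q


TABLE_CATEGORIES = ["Down/Down", "Down/Up", "Up/Down", "Up/Up"]


def classify_de(results: pd.DataFrame, contrasts: tuple[str, str],
                alpha: float = 0.05) -> tuple[pd.DataFrame, pd.Series]:
    """Two-line direction classification of jointly significant probes.

    A probe is jointly significant iff its FDR-adjusted p-value is
    <= ``alpha`` in BOTH contrasts; its category is the sign pair of the
    two log2 fold changes (Down/Down, Down/Up, Up/Down, Up/Up).  Returns
    the per-probe classification and the category counts plus total.
    """
    c1, c2 = contrasts
    cls = pd.DataFrame(index=results.index)
    for c in contrasts:
        coef = results[f"coef_{c}"]
        sig = results[f"q_{c}"] <= alpha
        direction = np.where(~sig, "ns",
                             np.where(coef > 0, "up",
                                      np.where(coef < 0, "down", "up")))
        if ((coef == 0) & sig).any():
            warnings.warn("zero fold change at significance; tie-broken up")
        cls[f"direction_{c}"] = direction
    joint = (cls[f"direction_{c1}"] != "ns") & (cls[f"direction_{c2}"] != "ns")
    labels = {"down": "Down", "up": "Up"}
    cat = pd.Series("not-significant", index=results.index, dtype=object)
    cat[joint] = (cls.loc[joint, f"direction_{c1}"].map(labels) + "/"
                  + cls.loc[joint, f"direction_{c2}"].map(labels))
    cls["category"] = cat
    counts = pd.Series({c: int((cat == c).sum()) for c in TABLE_CATEGORIES})
    counts["Total"] = int(joint.sum())
    return cls, counts


# ---------------------------------------------------------------------------
# model / results

class TwoColorDEModel:
    """Differential-expression model for a set of two-color arrays.

    Parameters
    ----------
    arrays : list of TwoColorArray
        Raw scanner tables, one per slide, each carrying its
        ``dye_orientation``.
    design : DataFrame
        One row per array (index = array_id), one column per contrast
        coefficient; entries are the usual 0/1 (or +-1) design codes on
        the already-orientation-corrected M scale.
    params : NormalizationParams, optional
    rho : float, optional
        Within-array duplicate-spot correlation; estimated from the data
        when omitted and duplicates are present.
    """

    def __init__(self, arrays: list[TwoColorArray], design: pd.DataFrame,
                 params: NormalizationParams | None = None,
                 rho: float | None = None):
        if len(arrays) != len(design):
            raise ValueError("one design row per array required")
        missing = {a.array_id for a in arrays} - set(design.index)
        if missing:
            raise ValueError(f"design missing rows for arrays {missing}")
        X = design.to_numpy(dtype=float)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design is not full rank")
        self.arrays = arrays
        self.design = design
        self.params = params or NormalizationParams()
        self.rho = rho

    @classmethod
    def from_gpr_files(cls, paths: list[str], targets: pd.DataFrame,
                       **kwargs) -> "TwoColorDEModel":
        """Build from GPR files plus a targets table.

        ``targets`` needs columns array_id, line, dye_orientation; one
        contrast coefficient is created per distinct line.
        """
        from xhyb.io import read_gpr
        arrays = []
        for path, (_, row) in zip(paths, targets.iterrows()):
            arrays.append(read_gpr(path, array_id=row["array_id"],
                                   dye_orientation=row["dye_orientation"]))
        lines = sorted(targets["line"].unique())
        design = pd.DataFrame(0.0, index=targets["array_id"], columns=lines)
        for _, row in targets.iterrows():
            design.loc[row["array_id"], row["line"]] = 1.0
        return cls(arrays, design, **kwargs)

    def normalize(self) -> list[MAData]:
        """Run steps 1-4 and return normalized M/A data per array."""
        mas = []
        for array in self.arrays:
            weights = flag_filter(array)
            corrected = normexp_background(
                array, offset=self.params.normexp_offset)
            ma = compute_MA(array, corrected, weights)
            mas.append(printtip_loess(ma, span=self.params.loess_span,
                                      iterations=self.params.loess_iterations))
        return mas

    def fit(self, alpha: float = 0.05,
            fdr_method: str = "bh") -> "DEResults":
        mas = self.normalize()
        rho = self.rho
        rho_estimated = False
        if rho is None:
            dups = find_duplicates(mas)
            if len(dups) >= MIN_DUPLICATE_PROBES:
                rho = duplicate_correlation(mas, dups)
                rho_estimated = True
            else:
                rho = 0.0
        fit = fit_linear_model(mas, self.design, rho=rho)
        coef_names = list(self.design.columns)
        moderated, hyper = ebayes_moderate(fit, coef_names)
        for name in coef_names:
            moderated[f"q_{name}"] = fdr_adjust(
                moderated[f"p_{name}"].to_numpy(), method=fdr_method)
        meta = {
            "rho": rho, "rho_estimated": rho_estimated,
            "rho_estimator": "trimmed Fisher-z consensus (not REML)",
            "fdr_method": fdr_method, "alpha": alpha,
            "normexp_offset": self.params.normexp_offset,
            "loess_span": self.params.loess_span,
            **hyper,
        }
        return DEResults(moderated, coef_names, meta, mas)


class DEResults:
    """Fit results: per-probe statistics plus classification helpers."""

    def __init__(self, table: pd.DataFrame, coef_names: list[str],
                 meta: dict, mas: list[MAData] | None = None):
        self.table = table
        self.coef_names = coef_names
        self.meta = meta
        self.mas = mas

    @property
    def d0(self) -> float:
        return self.meta["d0"]

    @property
    def s0_squared(self) -> float:
        return self.meta["s0_squared"]

    @property
    def rho(self) -> float:
        return self.meta["rho"]

    def classify(self, contrasts: tuple[str, str] | None = None,
                 alpha: float | None = None
                 ) -> tuple[pd.DataFrame, pd.Series]:
        if contrasts is None:
            if len(self.coef_names) != 2:
                raise ValueError("specify the two contrasts to classify")
            contrasts = tuple(self.coef_names)
        alpha = self.meta["alpha"] if alpha is None else alpha
        return classify_de(self.table, contrasts, alpha=alpha)

    def significant(self, contrast: str, alpha: float | None = None
                    ) -> pd.Index:
        alpha = self.meta["alpha"] if alpha is None else alpha
        q = self.table[f"q_{contrast}"]
        return self.table.index[q <= alpha]

    def summary(self) -> str:
        lines = [
            "Two-color differential expression fit",
            "=" * 45,
            f"probes fitted:        {len(self.table)}",
            f"contrasts:            {', '.join(self.coef_names)}",
            f"duplicate corr rho:   {self.meta['rho']:.4f}"
            + (" (estimated)" if self.meta["rho_estimated"] else " (given)"),
            f"prior df d0:          {self.d0:.4g}",
            f"prior variance s0^2:  {self.s0_squared:.4g}",
            f"FDR method:           {self.meta['fdr_method'].upper()}",
        ]
        alpha = self.meta["alpha"]
        for name in self.coef_names:
            n_sig = int((self.table[f"q_{name}"] <= alpha).sum())
            lines.append(f"significant ({name}, q<={alpha}): {n_sig}")
        if len(self.coef_names) == 2:
            _, counts = self.classify()
            lines.append("-" * 45)
            lines.append(f"jointly significant (both contrasts, "
                         f"q<={alpha}): {counts['Total']}")
            for cat in TABLE_CATEGORIES:
                lines.append(f"  {cat:<12} {counts[cat]}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")

    def plot_ma(self, array_index: int = 0, ax=None):
        """MA plot of one normalized array (requires matplotlib)."""
        import matplotlib.pyplot as plt
        if self.mas is None:
            raise ValueError("normalized M/A data not retained")
        ma = self.mas[array_index]
        if ax is None:
            _, ax = plt.subplots()
        ok = ma.data["weight"] > 0
        ax.scatter(ma.data.loc[ok, "A"], ma.data.loc[ok, "M"], s=4, alpha=0.4)
        ax.axhline(0.0, color="red", lw=0.8)
        ax.set_xlabel("A (mean log2 intensity)")
        ax.set_ylabel("M (log2 ratio)")
        ax.set_title(f"MA plot: {ma.array_id}")
        return ax
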