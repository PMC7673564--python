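"""Statistical comparison of perfusion metrics across areas and states.

Metric values are reciprocal-transformed (``y = 1/x``) before modelling to
tame right skew; summaries are back-transformed for reporting.  Effects of
area, hemodynamic state, and their interaction are assessed with a two-way
fixed-effects linear model whose p-values come from block permutations
(area labels permuted within animal x state blocks, state labels within
animal x area blocks, interaction via Freedman-Lane residual permutation
within animals).  Marginal-mean intervals come from a percentile bootstrap
over animals.  This deliberately replaces opaque mixed-model covariance
fitting with small-sample-honest resampling inference.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import defaults
from .errors import InvalidInputError, TransformError

__all__ = [
    "EffectSummary",
    "CorrelationResult",
    "inverse_transform",
    "back_transform",
    "area_time_model",
    "correlate_metric_with_flow",
    "summarize_ordering",
]

_TIE_EPS = 1e-12


# --------------------------------------------------------------- transforms


def inverse_transform(values):
    """Reciprocal transform ``y = 1/x``; every value must be > 0."""
    arr = np.asarray(values, dtype=float)
    bad = np.flatnonzero(~(arr > 0))
    if bad.size:
        raise TransformError(
            f"reciprocal transform needs positive values; offending row(s) "
            f"{bad.tolist()} with value(s) {arr[bad].tolist()}"
        )
    out = 1.0 / arr
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def back_transform(values):
    """Inverse of :func:`inverse_transform` (self-inverse)."""
    return inverse_transform(values)


# ------------------------------------------------------------------ results


@dataclass(frozen=True)
class EffectSummary:
    metric: str
    marginal_means: pd.DataFrame  # roi, state, mean, ci_low, ci_high
    p_area: float
    p_time: float
    p_interaction: float
    n_permutations: int
    seed: int | None
    exact: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    metric: str
    rho: float
    p_value: float
    n: int
    n_permutations: int
    method: str = "spearman"


# ----------------------------------------------------- design / F machinery


def _dummies(labels: pd.Series) -> np.ndarray:
    """Drop-first one-hot encoding with a deterministic level order."""
    levels = sorted(labels.unique())
    return np.column_stack(
        [(labels == lv).to_numpy(float) for lv in levels[1:]]
    ) if len(levels) > 1 else np.empty((len(labels), 0))


def _residual_projector(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    return np.eye(n) - x @ np.linalg.pinv(x)


def _rss(q: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residual sum of squares for each column of ``y`` under projector ``q``."""
    r = q @ y
    return np.einsum("ij,ij->j", r, r)


class _AnovaEngine:
    """Precomputed projectors for partial-F statistics of a two-way layout."""

    def __init__(self, roi: pd.Series, state: pd.Series):
        n = len(roi)
        xa = _dummies(roi)
        xs = _dummies(state)
        xi = np.column_stack(
            [xa[:, i] * xs[:, j] for i in range(xa.shape[1]) for j in range(xs.shape[1])]
        ) if xa.shape[1] and xs.shape[1] else np.empty((n, 0))
        one = np.ones((n, 1))
        x_full = np.hstack([one, xa, xs, xi])
        x_main = np.hstack([one, xa, xs])
        x_area = np.hstack([one, xa])
        x_state = np.hstack([one, xs])
        self.q_full = _residual_projector(x_full)
        self.q_main = _residual_projector(x_main)
        self.q_area = _residual_projector(x_area)
        self.q_state = _residual_projector(x_state)
        self.p_main = np.eye(n) - self.q_main
        self.df_area = xa.shape[1]
        self.df_state = xs.shape[1]
        self.df_inter = xi.shape[1]
        self.df_error = n - np.linalg.matrix_rank(x_full)
        if self.df_error <= 0:
            raise InvalidInputError(
                "no residual degrees of freedom; need replication (>= 2 animals)"
            )

    def _partial_f(self, y2d, q_red, q_big, df_num):
        rss_full = _rss(self.q_full, y2d)
        num = (_rss(q_red, y2d) - _rss(q_big, y2d)) / df_num
        den = rss_full / self.df_error
        out = np.zeros_like(den)
        ok = den > _TIE_EPS
        out[ok] = num[ok] / den[ok]
        # den ~ 0: perfect fit; any explained variation gives +inf F
        out[~ok & (num > _TIE_EPS)] = np.inf
        return out

    def f_area(self, y: np.ndarray) -> np.ndarray:
        return self._partial_f(np.atleast_2d(y.T).T if y.ndim == 1 else y,
                               self.q_state, self.q_main, self.df_area)

    def f_time(self, y: np.ndarray) -> np.ndarray:
        return self._partial_f(np.atleast_2d(y.T).T if y.ndim == 1 else y,
                               self.q_area, self.q_main, self.df_state)

    def f_interaction(self, y: np.ndarray) -> np.ndarray:
        return self._partial_f(np.atleast_2d(y.T).T if y.ndim == 1 else y,
                               self.q_main, self.q_full, self.df_inter)


def _as_col(y: np.ndarray) -> np.ndarray:
    return y.reshape(-1, 1)


def _block_indices(df: pd.DataFrame, cols: list[str]) -> list[np.ndarray]:
    return [np.asarray(v) for v in df.groupby(cols, sort=True).indices.values()]


def _permute_within_blocks(
    rng: np.random.Generator, blocks: list[np.ndarray], n: int, n_perm: int
) -> np.ndarray:
    """(n_perm, n) index matrix: each row permutes entries within blocks."""
    idx = np.tile(np.arange(n), (n_perm, 1))
    for blk in blocks:
        sub = np.tile(blk, (n_perm, 1))
        idx[:, blk] = rng.permuted(sub, axis=1)
    return idx


def _enumerate_within_blocks(blocks: list[np.ndarray], n: int, limit: int):
    """All within-block permutation index vectors (identity included)."""
    per_block = []
    total = 1
    for blk in blocks:
        perms = list(itertools.permutations(blk))
        per_block.append(perms)
        total *= len(perms)
        if total > limit:
            return None
    out = np.empty((total, n), dtype=int)
    for row, combo in enumerate(itertools.product(*per_block)):
        idx = np.arange(n)
        for blk, perm in zip(blocks, combo):
            idx[blk] = perm
        out[row] = idx
    return out


def _perm_pvalue(f_obs: float, f_perm: np.ndarray, exact: bool) -> float:
    hits = int(np.sum(f_perm >= f_obs - _TIE_EPS))
    if exact:
        return hits / len(f_perm)
    return (1 + hits) / (1 + len(f_perm))


# ------------------------------------------------------------------- model


def area_time_model(
    table: pd.DataFrame,
    metric_name: str,
    n_permutations: int = defaults.N_PERMUTATIONS,
    n_bootstrap: int = defaults.N_BOOTSTRAP,
    seed: int | None = 0,
    effects: tuple[str, ...] = ("area", "time", "interaction"),
    exact: bool | None = None,
    exact_limit: int = 100_000,
    mean_of_reciprocals: bool = False,
) -> EffectSummary:
    """Two-way fixed-effects comparison of a transformed metric.

    ``table`` is tidy with columns ``animal_id, roi, state`` and the metric
    column ``metric_name`` (strictly positive).  ``exact=True`` (or auto when
    the within-block permutation group is no larger than ``n_permutations``)
    enumerates every permutation instead of sampling.

    Marginal means are back-transformed from the transformed-scale cell mean
    (``mean_of_reciprocals=True`` switches to the mean of back-transformed
    values); 95% intervals come from a percentile bootstrap over animals and
    are widened, if necessary, to contain the point estimate.
    """
    required = {"animal_id", "roi", "state", metric_name}
    missing = required - set(table.columns)
    if missing:
        raise InvalidInputError(f"metrics table missing columns {sorted(missing)}")
    df = table.dropna(subset=[metric_name]).reset_index(drop=True)
    if df["roi"].nunique() < 2 or df["state"].nunique() < 2:
        raise InvalidInputError("need >= 2 areas and >= 2 states")
    counts = df.groupby(["roi", "state"])[metric_name].size()
    full_grid = df["roi"].nunique() * df["state"].nunique()
    if len(counts) < full_grid:
        raise InvalidInputError("a (roi, state) cell is completely empty")
    balanced = counts.nunique() == 1
    if not balanced:
        import warnings

        warnings.warn("unbalanced (roi, state) cells; fit proceeds", stacklevel=2)

    y = inverse_transform(df[metric_name]).to_numpy()
    rng = np.random.default_rng(seed)
    constant = float(np.ptp(y)) <= _TIE_EPS * max(1.0, abs(float(y[0])))

    engine = _AnovaEngine(df["roi"], df["state"])
    pvals = {"area": float("nan"), "time": float("nan"), "interaction": float("nan")}
    used_exact = False

    schemes = {
        "area": (engine.f_area, ["animal_id", "state"]),
        "time": (engine.f_time, ["animal_id", "roi"]),
    }
    for effect in effects:
        if constant:
            pvals[effect] = 1.0
            continue
        if effect in schemes:
            f_fn, block_cols = schemes[effect]
            f_obs = float(f_fn(_as_col(y))[0])
            blocks = _block_indices(df, block_cols)
            idx = None
            if exact or exact is None:
                idx = _enumerate_within_blocks(
                    blocks, len(y), min(exact_limit, n_permutations)
                    if exact is None else exact_limit
                )
                if idx is None and exact:
                    raise InvalidInputError(
                        "exact enumeration exceeds exact_limit"
                    )
            if idx is not None:
                f_perm = f_fn(y[idx].T)
                pvals[effect] = _perm_pvalue(f_obs, f_perm, exact=True)
                used_exact = True
            else:
                idx = _permute_within_blocks(rng, blocks, len(y), n_permutations)
                f_perm = f_fn(y[idx].T)
                pvals[effect] = _perm_pvalue(f_obs, f_perm, exact=False)
        elif effect == "interaction":
            # Freedman-Lane: permute main-effects residuals within animals.
            f_obs = float(engine.f_interaction(_as_col(y))[0])
            fitted = engine.p_main @ y
            resid = y - fitted
            blocks = _block_indices(df, ["animal_id"])
            idx = _permute_within_blocks(rng, blocks, len(y), n_permutations)
            y_star = fitted[:, None] + resid[idx].T
            f_perm = engine.f_interaction(y_star)
            pvals[effect] = _perm_pvalue(f_obs, f_perm, exact=False)
        else:
            raise InvalidInputError(f"unknown effect {effect!r}")

    marginal = _marginal_means(
        df, metric_name, n_bootstrap, rng, mean_of_reciprocals
    )
    return EffectSummary(
        metric=metric_name,
        marginal_means=marginal,
        p_area=pvals["area"],
        p_time=pvals["time"],
        p_interaction=pvals["interaction"],
        n_permutations=n_permutations,
        seed=seed,
        exact=used_exact,
    )


def _cell_means(df: pd.DataFrame, metric: str, mean_of_reciprocals: bool) -> pd.Series:
    if mean_of_reciprocals:
        return df.groupby(["roi", "state"])[metric].mean()
    transformed = df.assign(_t=1.0 / df[metric])
    return 1.0 / transformed.groupby(["roi", "state"])["_t"].mean()


def _marginal_means(
    df: pd.DataFrame,
    metric: str,
    n_bootstrap: int,
    rng: np.random.Generator,
    mean_of_reciprocals: bool,
) -> pd.DataFrame:
    point = _cell_means(df, metric, mean_of_reciprocals)
    animals = sorted(df["animal_id"].unique())
    groups = {a: g for a, g in df.groupby("animal_id")}
    boot = []
    for _ in range(n_bootstrap):
        chosen = rng.choice(animals, size=len(animals), replace=True)
        sample = pd.concat([groups[a] for a in chosen], ignore_index=True)
        boot.append(_cell_means(sample, metric, mean_of_reciprocals))
    boot_df = pd.DataFrame(boot)
    rows = []
    for (roi, state), est in point.items():
        col = boot_df.get((roi, state))
        vals = col.dropna().to_numpy() if col is not None else np.array([est])
        lo, hi = np.percentile(vals, [2.5, 97.5]) if vals.size else (est, est)
        rows.append(
            {
                "roi": roi,
                "state": state,
                "mean": float(est),
                "ci_low": float(min(lo, est)),
                "ci_high": float(max(hi, est)),
            }
        )
    return pd.DataFrame(rows).sort_values(["roi", "state"]).reset_index(drop=True)


# -------------------------------------------------------------- correlation


def correlate_metric_with_flow(
    metrics: pd.DataFrame,
    flows: pd.DataFrame,
    metric_name: str = "sfi",
    flow_column: str = "per_gram_flow_ml_min_g",
    n_permutations: int = defaults.N_PERMUTATIONS,
    seed: int | None = 0,
    method: str = "spearman",
) -> CorrelationResult:
    """Rank correlation between a FI metric and microsphere flow.

    Rows are matched on ``(animal_id, roi, state)``; the permutation null
    shuffles the flow values within animal blocks (two-sided p).
    """
    keys = ["animal_id", "roi", "state"]
    merged = metrics.merge(flows, on=keys, how="inner", validate="one_to_one")
    merged = merged.dropna(subset=[metric_name, flow_column]).reset_index(drop=True)
    if len(merged) < 3:
        raise InvalidInputError("need >= 3 matched (animal, roi, state) rows")
    x = merged[metric_name].to_numpy(float)
    y = merged[flow_column].to_numpy(float)

    if method == "spearman":
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
    elif method == "pearson":
        rx, ry = x, y
    else:
        raise InvalidInputError(f"unknown method {method!r}")
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc @ rxc) * (ryc @ ryc))
    if denom <= _TIE_EPS:
        raise InvalidInputError("degenerate (constant) inputs")
    rho = float(rxc @ ryc / denom)

    rng = np.random.default_rng(seed)
    blocks = _block_indices(merged, ["animal_id"])
    idx = _permute_within_blocks(rng, blocks, len(merged), n_permutations)
    # permuting values permutes ranks; norms are permutation-invariant
    rho_perm = (ryc[idx] @ rxc) / denom
    p = (1 + int(np.sum(np.abs(rho_perm) >= abs(rho) - _TIE_EPS))) / (
        1 + n_permutations
    )
    return CorrelationResult(
        metric=metric_name,
        rho=rho,
        p_value=float(p),
        n=len(merged),
        n_permutations=n_permutations,
        method=method,
    )


# ----------------------------------------------------------------- ordering


def summarize_ordering(
    table: pd.DataFrame, metrics: tuple[str, ...] = ("bsfi", "sfi", "tts_ratio")
) -> pd.DataFrame:
    """Per-state area ranking per metric, with the fraction of animals whose
    individual values share the across-animal mean ordering."""
    rows = []
    for metric in metrics:
        if metric not in table.columns:
            continue
        sub = table.dropna(subset=[metric])
        for state, grp in sub.groupby("state", sort=True):
            means = grp.groupby("roi")[metric].mean().sort_values(ascending=False)
            ordering = tuple(means.index)
            agree = 0
            animals = grp["animal_id"].unique()
            for animal in animals:
                g = grp[grp["animal_id"] == animal]
                vals = g.set_index("roi")[metric]
                if len(vals) == len(ordering) and tuple(
                    vals.sort_values(ascending=False).index
                ) == ordering:
                    agree += 1
            rows.append(
                {
                    "metric": metric,
                    "state": state,
                    "ordering": ">".join(ordering),
                    "agreement_fraction": agree / len(animals) if len(animals) else 0.0,
                    "n_animals": len(animals),
                }
            )
    return pd.DataFrame(rows)
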