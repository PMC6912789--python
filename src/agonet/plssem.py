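"""Partial least squares structural equation modeling (PLS-SEM), from scratch.

The structural model asks how much of latent *dominance* (D, measured
reflectively by DI1 and DI2) is explained by latent *centrality* constructs
of the two network flavors (C_IR and C_WL, measured by out-degree, outgoing
closeness and -- for the larger-pen age groups -- betweenness of the
respective network).  Estimation is the classical PLS path algorithm:

1. standardize all indicators (zero mean, unit variance, ``ddof=1``);
2. initialize each block's outer weights to +1;
3. iterate until the outer weights stabilize:
   a. latent scores = standardized weighted sums of their block's indicators,
   b. inner proxies by the *path weighting scheme*: a latent's proxy combines
      its predecessors weighted by the multiple-regression coefficients of
      the latent on them, and its successors weighted by score correlations,
   c. Mode A (reflective) outer-weight update: correlation of each indicator
      with its block's inner proxy;
4. loadings = correlations of indicators with their latent's final score;
   structural path coefficients by OLS among latent scores; R^2 of each
   endogenous latent from that regression.

Quality diagnostics: indicator reliability (squared loading, want > 0.7),
composite reliability ((sum |loading|)^2 / ((sum |loading|)^2 +
sum(1 - loading^2)), exploratory range 0.6-0.9), AVE (mean squared loading,
want > 0.5), and the R^2 verbal bands at 0.25 / 0.50 / 0.75.

Inference on the path coefficients uses the bootstrap: observations are
resampled with replacement, the model refit, each replicate's latents
sign-aligned with the original fit, and two-sided p-values taken from the
t statistic estimate/SE with ``n - 1`` degrees of freedom.  Standardized
path coefficients may legitimately exceed 1 in magnitude when exogenous
latents are collinear; they are never clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PlsModelSpec",
    "PlsModelFit",
    "default_model_spec",
    "fit_pls",
    "bootstrap_paths",
    "quality_gates",
]


@dataclass(frozen=True)
class PlsModelSpec:
    """Latent blocks and structural edges of a PLS path model.

    ``blocks`` maps each latent name to its (ordered) indicator columns;
    ``paths`` are directed structural edges (source, target) and must form
    an acyclic graph.  Measurement is reflective (Mode A) throughout.
    """

    blocks: Mapping[str, tuple[str, ...]]
    paths: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", dict(self.blocks))
        seen: set[str] = set()
        for latent, indicators in self.blocks.items():
            if not indicators:
                raise ValueError(f"latent {latent!r} has no indicators")
            dup = seen & set(indicators)
            if dup:
                raise ValueError(f"indicators {sorted(dup)} assigned to two latents")
            seen |= set(indicators)
        for src, dst in self.paths:
            if src not in self.blocks or dst not in self.blocks:
                raise ValueError(f"path ({src!r}, {dst!r}) uses unknown latent")
        if self._has_cycle():
            raise ValueError("structural graph must be acyclic")

    def _has_cycle(self) -> bool:
        order: dict[str, int] = {}
        visiting: set[str] = set()
        succ: dict[str, list[str]] = {l: [] for l in self.blocks}
        for s, d in self.paths:
            succ[s].append(d)

        def visit(v: str) -> bool:
            if v in order:
                return False
            if v in visiting:
                return True
            visiting.add(v)
            if any(visit(w) for w in succ[v]):
                return True
            visiting.discard(v)
            order[v] = len(order)
            return False

        return any(visit(v) for v in self.blocks)

    @property
    def latents(self) -> tuple[str, ...]:
        return tuple(self.blocks)

    @property
    def indicators(self) -> tuple[str, ...]:
        return tuple(i for block in self.blocks.values() for i in block)

    def predecessors(self, latent: str) -> tuple[str, ...]:
        return tuple(s for s, d in self.paths if d == latent)

    def successors(self, latent: str) -> tuple[str, ...]:
        return tuple(d for s, d in self.paths if s == latent)


@dataclass
class PlsModelFit:
    """Converged (or flagged) PLS estimate."""

    spec: PlsModelSpec
    n_obs: int
    converged: bool
    n_iter: int
    outer_weights: dict[str, float]
    loadings: dict[str, float]
    scores: pd.DataFrame
    path_coefficients: dict[tuple[str, str], float]
    r_squared: dict[str, float]
    indicator_reliability: dict[str, float] = field(default_factory=dict)
    composite_reliability: dict[str, float] = field(default_factory=dict)
    ave: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.indicator_reliability = {k: v**2 for k, v in self.loadings.items()}
        cr: dict[str, float] = {}
        ave: dict[str, float] = {}
        for latent, indicators in self.spec.blocks.items():
            lam = np.array([self.loadings[i] for i in indicators])
            ssum = np.abs(lam).sum() ** 2
            cr[latent] = ssum / (ssum + np.sum(1.0 - lam**2))
            ave[latent] = float(np.mean(lam**2))
        self.composite_reliability = cr
        self.ave = ave


def default_model_spec(profile: str) -> PlsModelSpec:
    """The dominance-vs-centrality model for an age group.

    All age groups relate D (indicators DI1, DI2) to C_IR and C_WL measured
    by out-degree and outgoing closeness; the larger-pen fattener and gilt
    groups additionally include IR betweenness in C_IR.
    """
    c_ir = ["ir_out_degree", "ir_closeness_out"]
    if profile in ("fattener", "gilt"):
        c_ir.append("ir_betweenness")
    elif profile != "piglet":
        raise ValueError(f"unknown profile {profile!r}")
    return PlsModelSpec(
        blocks={
            "C_IR": tuple(c_ir),
            "C_WL": ("wl_out_degree", "wl_closeness_out"),
            "D": ("di1", "di2"),
        },
        paths=(("C_IR", "D"), ("C_WL", "D")),
    )


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant indicator: cannot standardize")
    return (x - x.mean(axis=0)) / sd


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.dot(a - a.mean(), b - b.mean()) / (
        (len(a) - 1) * a.std(ddof=1) * b.std(ddof=1)
    ))


def fit_pls(
    data: pd.DataFrame,
    spec: PlsModelSpec,
    tol: float = 1e-7,
    max_iter: int = 300,
    min_obs: int = 10,
) -> PlsModelFit:
    """Fit the PLS path model on complete cases of ``data``.

    Rows with any missing indicator (isolated animals without a dominance
    index) are dropped.  Raises on constant indicators or too few
    observations; non-convergence is flagged on the result, not raised.
    """
    cols = list(spec.indicators)
    frame = data[cols].dropna()
    n = len(frame)
    if n < min_obs:
        raise ValueError(f"need at least {min_obs} complete cases, got {n}")
    X = _standardize(frame.to_numpy(dtype=float))
    idx_of = {c: k for k, c in enumerate(cols)}
    block_idx = {
        latent: np.array([idx_of[i] for i in indicators])
        for latent, indicators in spec.blocks.items()
    }
    weights = {latent: np.ones(len(ix)) for latent, ix in block_idx.items()}

    def block_scores(w: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
        scores = {}
        for latent, ix in block_idx.items():
            y = X[:, ix] @ w[latent]
            sd = y.std(ddof=1)
            if sd == 0:
                raise ValueError(f"degenerate score for latent {latent!r}")
            y = y / sd
            # sign convention: positive correlation with the first indicator
            if _corr(y, X[:, ix[0]]) < 0:
                y = -y
            scores[latent] = y
        return scores

    converged = False
    n_iter = 0
    scores = block_scores(weights)
    for n_iter in range(1, max_iter + 1):
        # inner proxies, path weighting scheme
        proxies: dict[str, np.ndarray] = {}
        for latent in spec.latents:
            z = np.zeros(n)
            preds = spec.predecessors(latent)
            if preds:
                P = np.column_stack([scores[p] for p in preds])
                coef, *_ = np.linalg.lstsq(
                    np.column_stack([np.ones(n), P]), scores[latent], rcond=None
                )
                z = z + P @ coef[1:]
            for succ in spec.successors(latent):
                z = z + _corr(scores[latent], scores[succ]) * scores[succ]
            if np.allclose(z, 0):
                raise ValueError(f"latent {latent!r} is disconnected")
            proxies[latent] = z
        # Mode A outer-weight update
        new_weights = {
            latent: np.array([_corr(X[:, j], proxies[latent]) for j in ix])
            for latent, ix in block_idx.items()
        }
        # compare on the unit-variance-score scale
        def _scaled(w: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
            out = {}
            for latent, ix in block_idx.items():
                y = X[:, ix] @ w[latent]
                scale = y.std(ddof=1)
                wv = w[latent] / scale
                if _corr(X[:, ix] @ wv, X[:, ix[0]]) < 0:
                    wv = -wv
                out[latent] = wv
            return out

        old_s, new_s = _scaled(weights), _scaled(new_weights)
        delta = max(
            float(np.max(np.abs(old_s[l] - new_s[l]))) for l in spec.latents
        )
        weights = new_weights
        scores = block_scores(weights)
        if delta < tol:
            converged = True
            break

    final_weights = {}
    loadings = {}
    for latent, ix in block_idx.items():
        y = X[:, ix] @ weights[latent]
        scale = y.std(ddof=1)
        w = weights[latent] / scale
        if _corr(X[:, ix] @ w, X[:, ix[0]]) < 0:
            w = -w
        for k, indicator in zip(range(len(ix)), spec.blocks[latent]):
            final_weights[indicator] = float(w[k])
            loadings[indicator] = _corr(X[:, ix[k]], scores[latent])

    paths: dict[tuple[str, str], float] = {}
    r2: dict[str, float] = {}
    for latent in spec.latents:
        preds = spec.predecessors(latent)
        if not preds:
            continue
        P = np.column_stack([np.ones(n)] + [scores[p] for p in preds])
        coef, *_ = np.linalg.lstsq(P, scores[latent], rcond=None)
        fittedv = P @ coef
        for p, c in zip(preds, coef[1:]):
            paths[(p, latent)] = float(c)
        ss_tot = float(np.sum((scores[latent] - scores[latent].mean()) ** 2))
        r2[latent] = 1.0 - float(np.sum((scores[latent] - fittedv) ** 2)) / ss_tot

    return PlsModelFit(
        spec=spec,
        n_obs=n,
        converged=converged,
        n_iter=n_iter,
        outer_weights=final_weights,
        loadings=loadings,
        scores=pd.DataFrame({l: scores[l] for l in spec.latents}, index=frame.index),
        path_coefficients=paths,
        r_squared=r2,
    )


@dataclass
class BootstrapResult:
    """Bootstrap standard errors and p-values for the structural paths."""

    n_boot: int
    n_failed: int
    estimates: dict[tuple[str, str], float]
    se: dict[tuple[str, str], float]
    p_values: dict[tuple[str, str], float]
    replicates: pd.DataFrame


def bootstrap_paths(
    data: pd.DataFrame,
    spec: PlsModelSpec,
    n_boot: int = 5000,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 300,
) -> BootstrapResult:
    """Bootstrap inference on the path coefficients.

    Resamples complete cases with replacement, refits, aligns each
    replicate's latent signs with the original fit (by the dot product of
    its loadings with the original block loadings), and reports SE (the
    replicate standard deviation) and two-sided p from the t statistic
    ``estimate / SE`` with ``n - 1`` degrees of freedom.  Replicates that
    fail to fit are counted; more than 5% failures raises a warning flag in
    the returned counts.
    """
    if n_boot < 500:
        raise ValueError("use at least 500 bootstrap replicates")
    base = fit_pls(data, spec, tol=tol, max_iter=max_iter)
    frame = data[list(spec.indicators)].dropna().reset_index(drop=True)
    n = len(frame)
    rng = np.random.default_rng(seed)
    rows = []
    n_failed = 0
    for _ in range(n_boot):
        take = rng.integers(0, n, size=n)
        sample = frame.iloc[take]
        try:
            fit = fit_pls(sample, spec, tol=tol, max_iter=max_iter, min_obs=2)
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        # sign-align each latent with the original solution
        flip = {}
        for latent, indicators in spec.blocks.items():
            dot = sum(
                fit.loadings[i] * base.loadings[i] for i in indicators
            )
            flip[latent] = -1.0 if dot < 0 else 1.0
        rows.append(
            {
                pth: flip[pth[0]] * flip[pth[1]] * coef
                for pth, coef in fit.path_coefficients.items()
            }
        )
    reps = pd.DataFrame(rows)
    se = {}
    p_values = {}
    for pth, est in base.path_coefficients.items():
        sd = float(reps[pth].std(ddof=1)) if len(reps) > 1 else math.nan
        se[pth] = sd
        if sd and sd > 0:
            t = est / sd
            p_values[pth] = float(2.0 * stats.t.sf(abs(t), n - 1))
        else:
            p_values[pth] = math.nan
    return BootstrapResult(
        n_boot=n_boot,
        n_failed=n_failed,
        estimates=dict(base.path_coefficients),
        se=se,
        p_values=p_values,
        replicates=reps,
    )


def r2_band(r2: float) -> str:
    """Verbal band for a coefficient of determination (0.25 / 0.50 / 0.75)."""
    if r2 >= 0.75:
        return "substantial"
    if r2 >= 0.50:
        return "moderate"
    if r2 >= 0.25:
        return "weak"
    return "below weak"


def quality_gates(fit: PlsModelFit) -> pd.DataFrame:
    """Outer/inner-model quality report.

    One row per check: indicator reliability > 0.7 per indicator, composite
    reliability within the exploratory 0.6-0.9 range per latent, AVE > 0.5
    per latent, and the verbal R^2 band per endogenous latent.
    """
    rows = []
    for indicator, rel in fit.indicator_reliability.items():
        rows.append(
            {
                "criterion": "indicator_reliability",
                "target": indicator,
                "value": rel,
                "passed": rel > 0.7,
                "note": "> 0.7",
            }
        )
    for latent, cr in fit.composite_reliability.items():
        rows.append(
            {
                "criterion": "composite_reliability",
                "target": latent,
                "value": cr,
                "passed": 0.6 <= cr <= 0.9,
                "note": "0.6-0.9 (exploratory)",
            }
        )
    for latent, ave in fit.ave.items():
        rows.append(
            {
                "criterion": "ave",
                "target": latent,
                "value": ave,
                "passed": ave > 0.5,
                "note": "> 0.5",
            }
        )
    for latent, r2 in fit.r_squared.items():
        rows.append(
            {
                "criterion": "r_squared",
                "target": latent,
                "value": r2,
                "passed": r2 >= 0.25,
                "note": r2_band(r2),
            }
        )
    return pd.DataFrame(rows)
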