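"""Noise-ceiling estimation via extrapolated brain-to-brain predictivity.

Measurement noise bounds how well *any* model can predict single-voxel
responses.  The ceiling is estimated by predicting each participant's
voxels from the pooled voxel responses of m other participants (their
matrices concatenated as features, mapped with the same cross-validated OLS
pipeline used for model-to-brain scoring), then extrapolating the voxelwise
predictivity v(m) to an infinitely large predictor pool and aggregating
voxel ceilings by the median.

The default extrapolation is the ratio form
``v(m) = v_inf * m / (m + tau)``: under additive measurement noise the true
curve is ``v_inf / sqrt(1 + b/m)``, which the ratio form tracks closely over
small pools, whereas a saturating exponential
(``form="saturating_exp"``) saturates too fast and underestimates the
asymptote.  Aggregation can be switched from median to mean.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .encode import BrainDataset, SplitScheme, fit_linear_map, make_folds, score_heldout
from .perturb import seed_for

__all__ = ["NoiseCeilingModel", "CeilingResults", "estimate_ceiling"]


def _sat_exp(m, v_inf, tau):
    return v_inf * (1.0 - np.exp(-np.asarray(m, dtype=float) / tau))


def _ratio(m, v_inf, tau):
    m = np.asarray(m, dtype=float)
    return v_inf * m / (m + tau)


_FORMS = {"saturating_exp": _sat_exp, "ratio": _ratio}


def _extrapolate(pool_sizes: np.ndarray, v: np.ndarray, form: str) -> tuple[float, float, bool]:
    """Fit v(m) and return (asymptote, tau, converged)."""
    fn = _FORMS[form]
    v = np.asarray(v, dtype=float)
    if np.allclose(v, v[0]):
        return float(v[0]), 1.0, True
    p0 = (float(np.clip(v[-1], -0.9, 0.9)) or 0.1, 1.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                fn, pool_sizes, v, p0=p0,
                bounds=([-1.0, 1e-3], [1.0, 1e3]), maxfev=10_000,
            )
        return float(popt[0]), float(popt[1]), True
    except (RuntimeError, ValueError):
        return float(v[-1]), float("nan"), False


class NoiseCeilingModel:
    """Brain-to-brain predictivity model for a set of overlapping participants.

    Parameters
    ----------
    brain : responses for participants with full stimulus overlap (>= 3).
    pool_sizes : predictor-pool sizes to subsample; defaults to
        1 .. n_participants - 1.
    n_iter : random predictor subsets drawn per (target, pool size).
    scheme : cross-validation scheme reused from the encoding pipeline.
    form : extrapolation functional form ("ratio" or "saturating_exp").
    aggregate : "median" (default) or "mean" over voxel ceilings.
    pooling : how predictor participants are combined — "mean" (default)
        averages their voxel matrices, so the feature count stays fixed and
        v(m) grows monotonically as predictor noise averages out; "concat"
        stacks them as extra features, which lets OLS overfit at large pools
        when sentences are few.
    """

    def __init__(
        self,
        brain: BrainDataset,
        pool_sizes: Sequence[int] | None = None,
        n_iter: int = 3,
        scheme: SplitScheme = SplitScheme(),
        form: str = "ratio",
        aggregate: str = "median",
        pooling: str = "mean",
    ) -> None:
        if len(brain.participants) < 3:
            raise ValueError("need at least 3 overlapping participants")
        if form not in _FORMS:
            raise ValueError(f"unknown form: {form}")
        if aggregate not in ("median", "mean"):
            raise ValueError("aggregate must be 'median' or 'mean'")
        if pooling not in ("mean", "concat"):
            raise ValueError("pooling must be 'mean' or 'concat'")
        self.pooling = pooling
        max_pool = len(brain.participants) - 1
        self.brain = brain
        self.pool_sizes = sorted(pool_sizes) if pool_sizes else list(range(1, max_pool + 1))
        if max(self.pool_sizes) > max_pool:
            raise ValueError(f"pool size exceeds available predictors ({max_pool})")
        self.n_iter = n_iter
        self.scheme = scheme
        self.form = form
        self.aggregate = aggregate

    def fit(self, seed: int = 0) -> "CeilingResults":
        brain = self.brain
        ids = list(brain.sentence_ids)
        passage_of = {sid: sid for sid in ids}  # unit=sentence only here
        folds = make_folds(ids, passage_of, SplitScheme(self.scheme.k, "sentence", seed_for(seed, "ceiling-folds")))
        participants = brain.participants
        curve_rows: list[dict] = []
        voxel_ceilings: dict[str, np.ndarray] = {}
        diagnostics: dict[str, dict] = {}
        for t_idx, target in enumerate(participants):
            predictors = [p for p in participants if p != target]
            Y = brain.responses[target]
            n_vox = Y.shape[1]
            v_curve = np.zeros((len(self.pool_sizes), n_vox))
            for si, m in enumerate(self.pool_sizes):
                iter_r = np.zeros((self.n_iter, n_vox))
                for it in range(self.n_iter):
                    # seed by position, not name, so the estimate is
                    # invariant to participant relabeling
                    rng = np.random.default_rng(seed_for(seed, "pool", t_idx, m, it))
                    chosen = list(rng.choice(predictors, size=m, replace=False))
                    mats = [brain.responses[p] for p in chosen]
                    if self.pooling == "mean":
                        if len({mat.shape[1] for mat in mats}) != 1:
                            raise ValueError("mean pooling needs equal voxel counts")
                        X = np.mean(mats, axis=0)
                    else:
                        X = np.hstack(mats)
                    fold_r = np.zeros((self.scheme.k, n_vox))
                    for fold in range(self.scheme.k):
                        tr = folds != fold
                        te = folds == fold
                        W = fit_linear_map(X[tr], Y[tr])
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            fold_r[fold] = score_heldout(W, X[te], Y[te])
                    iter_r[it] = fold_r.mean(axis=0)
                v_curve[si] = iter_r.mean(axis=0)
                curve_rows.append(
                    {"target": target, "pool_size": m, "mean_predictivity": float(v_curve[si].mean())}
                )
            ceilings = np.zeros(n_vox)
            n_failed = 0
            taus = np.zeros(n_vox)
            for v in range(n_vox):
                ceilings[v], taus[v], ok = _extrapolate(
                    np.asarray(self.pool_sizes, dtype=float), v_curve[:, v], self.form
                )
                n_failed += not ok
            voxel_ceilings[target] = ceilings
            diagnostics[target] = {
                "n_voxels": int(n_vox),
                "n_fit_failures": int(n_failed),
                "median_tau": float(np.nanmedian(taus)),
            }
        all_ceil = np.concatenate(list(voxel_ceilings.values()))
        agg = np.median if self.aggregate == "median" else np.mean
        asymptote = float(agg(all_ceil))
        return CeilingResults(
            model=self,
            asymptote=asymptote,
            voxel_ceilings=voxel_ceilings,
            curve=pd.DataFrame(curve_rows),
            diagnostics=diagnostics,
            seed=seed,
        )


@dataclass
class CeilingResults:
    """Noise ceiling estimate with the subsample curve and diagnostics."""

    model: NoiseCeilingModel
    asymptote: float
    voxel_ceilings: dict[str, np.ndarray]
    curve: pd.DataFrame
    diagnostics: dict
    seed: int = 0

    def mean_curve(self) -> pd.Series:
        """Mean predictivity per pool size, averaged over targets."""
        return self.curve.groupby("pool_size")["mean_predictivity"].mean()

    def summary(self) -> str:
        lines = [
            "Noise ceiling (brain-to-brain predictivity)",
            "===========================================",
            f"participants:   {len(self.model.brain.participants)}",
            f"pool sizes:     {self.model.pool_sizes}",
            f"form:           {self.model.form}",
            f"aggregate:      {self.model.aggregate}",
            f"ceiling:        {self.asymptote:.4f}",
            "",
            "subsample curve (mean over targets and voxels):",
        ]
        for m, v in self.mean_curve().items():
            lines.append(f"  pool size {m:>2d}: {v:+.4f}")
        failures = sum(d["n_fit_failures"] for d in self.diagnostics.values())
        if failures:
            lines.append(f"warning: {failures} voxel fits did not converge (raw curve kept)")
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "asymptote": self.asymptote,
            "form": self.model.form,
            "aggregate": self.model.aggregate,
            "pool_sizes": list(self.model.pool_sizes),
            "n_iter": self.model.n_iter,
            "seed": self.seed,
            "curve": self.curve.to_dict(orient="records"),
            "voxel_ceilings": {k: v.tolist() for k, v in self.voxel_ceilings.items()},
            "diagnostics": self.diagnostics,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def estimate_ceiling(
    brain: BrainDataset,
    pool_sizes: Sequence[int] | None = None,
    n_iter: int = 3,
    seed: int = 0,
    **kwargs,
) -> CeilingResults:
    """Functional wrapper over :class:`NoiseCeilingModel`."""
    return NoiseCeilingModel(brain, pool_sizes=pool_sizes, n_iter=n_iter, **kwargs).fit(seed=seed)
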