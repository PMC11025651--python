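"""Statistics over score tables, representational similarity, surprisal.

Three analysis families:

* condition contrasts — pairwise two-sided dependent-samples t tests over
  participant scores, Bonferroni-corrected within a declared comparison
  family, plus within-participant-centered MAD error values;
* representational similarity — per-sentence Spearman rank correlation
  between the summary vectors of the original and a perturbed condition,
  averaged over sentences, per layer; and its Pearson correlation with
  predictivity over (condition x layer) cells;
* surprisal — mean token surprisal (nats) of each condition's strings under
  a next-token language-model provider, and the correlation between
  condition-level surprisal deltas and predictivity deltas relative to the
  Original condition (the sentence-replacement category is excluded, since
  its strings are drawn from the same material set and bear no relation to
  the original string).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .encode import ScoreTable, select_best_layer
from .perturb import CONDITION_CATEGORY, PerturbedStimulus
from .represent import RepresentationStore

__all__ = [
    "StatsResult",
    "dependent_ttests",
    "mad_within_participants",
    "rsa_similarity",
    "similarity_table",
    "similarity_predictivity_correlation",
    "LanguageModelProvider",
    "mean_surprisal",
    "surprisal_table",
    "surprisal_predictivity_correlation",
]

#: Normal-consistency scale for the MAD (1 / Phi^-1(3/4)).
MAD_SCALE = 1.4826022185056018


@dataclass
class StatsResult:
    """Pairwise dependent-t comparisons with Bonferroni correction."""

    comparisons: pd.DataFrame  # condition_a, condition_b, t, p_raw, p_bonferroni, family
    family_sizes: dict[str, int] = field(default_factory=dict)


def dependent_ttests(
    scores: Mapping[str, Sequence[float]],
    pairs: Sequence[tuple[str, str]] | None = None,
    family: str = "all",
) -> StatsResult:
    """Two-sided paired t tests between conditions' participant scores.

    ``scores`` maps condition name to the per-participant score vector
    (aligned across conditions).  Comparing a condition against the literal
    name ``"0"`` runs a one-sample t test against zero.  P values are
    Bonferroni-corrected by the number of comparisons in the family.
    """
    conds = list(scores)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(conds) for b in conds[i + 1:]]
    m = len(pairs)
    rows = []
    for a, b in pairs:
        x = np.asarray(scores[a], dtype=float)
        if b == "0":
            y = np.zeros_like(x)
        else:
            y = np.asarray(scores[b], dtype=float)
        if x.shape != y.shape or x.size < 2:
            raise ValueError(f"paired vectors for ({a}, {b}) must have equal length >= 2")
        d = x - y
        if np.allclose(d, d[0]):
            if np.allclose(d, 0):
                t, p = 0.0, 1.0
            else:
                t, p = math.inf if d[0] > 0 else -math.inf, 0.0
            undefined = not np.allclose(d, 0)
        else:
            t, p = stats.ttest_rel(x, y)
            undefined = False
        rows.append(
            {
                "condition_a": a,
                "condition_b": b,
                "t": float(t),
                "p_raw": float(p),
                "p_bonferroni": float(min(1.0, p * m)),
                "family": family,
                "zero_variance": bool(undefined),
            }
        )
    return StatsResult(pd.DataFrame(rows), {family: m})


def mad_within_participants(
    scores: Mapping[str, Sequence[float]],
    scale: float = MAD_SCALE,
) -> dict[str, float]:
    """Within-participant-centered MAD error per condition.

    ``scores`` maps the conditions of one manipulation category to aligned
    per-participant score vectors.  Each participant's across-condition mean
    is subtracted (removing between-participant offsets) and the MAD over
    participants is computed per condition with normal-consistency scaling,
    so the error bars reflect within-participant variation across conditions.
    """
    conds = list(scores)
    if len(conds) < 2:
        raise ValueError("need at least 2 conditions in the category")
    mat = np.asarray([scores[c] for c in conds], dtype=float)  # (n_cond, n_part)
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 participants")
    centered = mat - mat.mean(axis=0, keepdims=True)
    mads = stats.median_abs_deviation(centered, axis=1, scale=1 / scale)
    return {c: float(v) for c, v in zip(conds, mads)}


# ---------------------------------------------------------------------------
# Representational similarity
# ---------------------------------------------------------------------------


def rsa_similarity(
    store_original: RepresentationStore,
    store_condition: RepresentationStore,
    layer: int,
) -> float:
    """Mean per-sentence Spearman correlation between summary vectors.

    For every sentence, the components of the original and perturbed
    summary vectors at ``layer`` (0-based) are rank-correlated; the mean
    over sentences is returned.  Sentences with a constant vector are
    skipped with a warning.
    """
    ids = store_original.sentence_ids
    if set(ids) != set(store_condition.sentence_ids):
        raise ValueError("stores cover different sentences")
    rhos = []
    skipped = 0
    for sid in ids:
        a = store_original.vector(sid, layer)
        b = store_condition.vector(sid, layer)
        if np.allclose(a, a[0]) or np.allclose(b, b[0]):
            skipped += 1
            continue
        if np.array_equal(a, b):
            rhos.append(1.0)
            continue
        rho, _ = stats.spearmanr(a, b)
        rhos.append(float(rho))
    if skipped:
        warnings.warn(f"{skipped} sentence(s) skipped (constant summary vector)")
    if not rhos:
        raise ValueError("no sentence had a non-constant summary vector")
    return float(np.mean(rhos))


def similarity_table(
    stores: Mapping[str, RepresentationStore],
    original: str = "Original",
) -> pd.DataFrame:
    """Mean rank-correlation similarity per (condition, layer), tidy."""
    if original not in stores:
        raise ValueError("need an Original store")
    base = stores[original]
    rows = []
    for cond, store in stores.items():
        for layer in range(base.n_layers):
            rows.append(
                {
                    "condition": cond,
                    "layer": layer + 1,
                    "similarity": rsa_similarity(base, store, layer),
                }
            )
    return pd.DataFrame(rows)


def similarity_predictivity_correlation(
    similarity: pd.DataFrame,
    scores: ScoreTable,
) -> tuple[float, pd.DataFrame]:
    """Pearson r between similarity and predictivity over (condition, layer).

    One point per (condition, layer) cell; predictivity is the
    across-participant median (experiments averaged within participant
    first).  Both tables must cover the same conditions and layers.
    """
    med = (
        scores.participant_scores()
        .groupby(["condition", "layer"], as_index=False)["score"]
        .median()
    )
    merged = similarity.merge(med, on=["condition", "layer"], how="outer")
    if merged[["similarity", "score"]].isna().any().any():
        raise ValueError("similarity and score tables do not cover the same cells")
    r, _ = stats.pearsonr(merged["similarity"], merged["score"])
    return float(r), merged


# ---------------------------------------------------------------------------
# Surprisal
# ---------------------------------------------------------------------------


class LanguageModelProvider(Protocol):
    """Contract: next-token surprisal in nats."""

    def surprisal(self, word: str, prev: str | None) -> float:
        """-ln p(word | prev); ``prev`` is None at string start."""
        ...


def mean_surprisal(
    stimuli: Mapping[str, PerturbedStimulus] | Mapping[str, Sequence[str]],
    lm: LanguageModelProvider,
) -> float:
    """Condition-level mean of per-string mean token surprisal (nats)."""
    values = []
    for sid, item in stimuli.items():
        words = list(item.surfaces) if isinstance(item, PerturbedStimulus) else list(item)
        if not words:
            continue
        s = 0.0
        prev: str | None = None
        for w in words:
            s += lm.surprisal(w, prev)
            prev = w
        values.append(s / len(words))
    if not values:
        raise ValueError("no non-empty strings to score")
    return float(np.mean(values))


def surprisal_table(
    condition_stimuli: Mapping[str, Mapping[str, PerturbedStimulus]],
    lm: LanguageModelProvider,
    original: str = "Original",
) -> pd.DataFrame:
    """Mean surprisal per condition plus delta vs the Original condition."""
    if original not in condition_stimuli:
        raise ValueError("need the Original condition")
    rows = []
    base = mean_surprisal(condition_stimuli[original], lm)
    for cond, stims in condition_stimuli.items():
        v = mean_surprisal(stims, lm)
        rows.append(
            {
                "condition": cond,
                "category": CONDITION_CATEGORY.get(cond, "unknown"),
                "mean_surprisal": v,
                "delta_surprisal": v - base,
            }
        )
    return pd.DataFrame(rows)


def surprisal_predictivity_correlation(
    surprisal: pd.DataFrame,
    scores: ScoreTable,
    exclude_categories: Sequence[str] = ("semantic-distance",),
    layer_policy: str = "per_condition",
) -> tuple[float, pd.DataFrame]:
    """Pearson r between condition-level surprisal and predictivity deltas.

    Predictivity per condition is the best-layer across-participant median.
    Following the usual sign convention, the surprisal delta is the
    condition's *increase* over Original while the predictivity delta is
    the *drop* from Original, so a monotone "more surprising, less
    predictive" link yields a positive correlation.  The sentence-
    replacement category is excluded by default (its strings bear no
    relation to the original string).
    """
    best = select_best_layer(scores, policy=layer_policy)
    if "Original" not in best:
        raise ValueError("score table lacks the Original condition")
    base_score = best["Original"][1]
    df = surprisal[~surprisal["category"].isin(exclude_categories)].copy()
    df["delta_predictivity"] = [
        base_score - best[c][1] if c in best else np.nan for c in df["condition"]
    ]
    if df["delta_predictivity"].isna().any():
        missing = df.loc[df["delta_predictivity"].isna(), "condition"].tolist()
        raise ValueError(f"score table lacks conditions: {missing}")
    pts = df[df["condition"] != "Original"]
    if len(pts) < 3:
        raise ValueError("need at least 3 condition points")
    r, _ = stats.pearsonr(pts["delta_surprisal"], pts["delta_predictivity"])
    return float(r), df


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------


def plot_condition_scores(scores: ScoreTable, path=None, policy: str = "per_condition"):
    """Best-layer predictivity bars per condition with within-participant
    MAD error bars, grouped by manipulation category."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    best = select_best_layer(scores, policy=policy)
    conds = scores.conditions()
    cats = [CONDITION_CATEGORY.get(c, "unknown") for c in conds]
    # MAD per category needs aligned participant vectors at the best layer
    errors: dict[str, float] = {c: 0.0 for c in conds}
    for cat in set(cats):
        members = [c for c, k in zip(conds, cats) if k == cat]
        if len(members) < 2:
            continue
        vectors = {}
        for c in members:
            ps = scores.participant_scores(c)
            ps = ps[ps["layer"] == best[c][0]].sort_values("participant")
            vectors[c] = ps["score"].to_numpy()
        if len({len(v) for v in vectors.values()}) == 1 and len(next(iter(vectors.values()))) >= 2:
            errors.update(mad_within_participants(vectors))
    fig, ax = plt.subplots(figsize=(max(6, 0.5 * len(conds)), 3.5))
    xs = np.arange(len(conds))
    colors = {
        "original": "#444444", "word-order": "#4878d0", "information-loss": "#ee854a",
        "semantic-distance": "#6acc64", "control": "#956cb4", "unknown": "#999999",
    }
    ax.bar(
        xs, [best[c][1] for c in conds],
        yerr=[errors[c] for c in conds],
        color=[colors[k] for k in cats], capsize=2,
    )
    ax.set_xticks(xs)
    ax.set_xticklabels(conds, rotation=60, ha="right", fontsize=7)
    ax.set_ylabel("best-layer predictivity (r)")
    ax.axhline(0, color="k", lw=0.5)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
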