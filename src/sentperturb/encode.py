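"""Voxelwise linear encoding models: folds, OLS mapping, scoring, designs.

The benchmark asks how well per-layer sentence representations linearly
predict held-out voxel responses.  Stimuli are split into k cross-validation
folds (by sentence, or by passage so that no passage straddles folds); for
each fold an ordinary-least-squares map with intercept is fitted per voxel
from training representations to training responses, and held-out
predictions are scored against measured responses with Pearson r.  Per-voxel
r is averaged over folds, the median over a participant's voxels is that
participant's score, experiments are processed separately and participant
scores averaged across them.

Two design factors are crossed: the mapping model can be trained on intact
(Original) or perturbed representations, and representations can be
contextualized by the preceding in-passage sentences or not.  Under the
train-on-intact design the sentence-replacement conditions (RandSent,
RandSentFromPassage, RandSentFromTopic) are realized at test time by
deranging the *original* sentences' representations within each test fold
(grouped by passage/topic where applicable), exactly because training and
test sets must stay disjoint; singleton groups cannot be deranged and are
logged as the unshuffled fraction.

The user-facing surface is statsmodels-style: build an
:class:`EncodingModel` from data and call :meth:`~EncodingModel.fit` to get
an :class:`EncodingResults` carrying the score table, per-fold voxel detail,
and a ``summary()``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import StimulusSet
from .perturb import CONDITION_CATEGORY, group_constrained_shuffle, derange, seed_for
from .represent import RepresentationStore

__all__ = [
    "BrainDataset",
    "SplitScheme",
    "Design",
    "ScoreTable",
    "EncodingModel",
    "EncodingResults",
    "make_folds",
    "fit_linear_map",
    "predict",
    "score_heldout",
    "apply_test_shuffle",
    "run_benchmark",
    "select_best_layer",
]

_SHUFFLED_CONDITIONS = ("RandSent", "RandSentFromPassage", "RandSentFromTopic")


@dataclass
class BrainDataset:
    """Per-participant sentence x voxel response matrices.

    ``responses[pid]`` has one row per sentence in ``sentence_ids`` order;
    no missing values.  ``ground_truth`` optionally carries the generative
    parameters of synthetic data.
    """

    sentence_ids: list[str]
    experiment_of: dict[str, str]
    responses: dict[str, np.ndarray]
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        n = len(self.sentence_ids)
        for pid, mat in self.responses.items():
            mat = np.asarray(mat, dtype=float)
            if mat.ndim != 2 or mat.shape[0] != n:
                raise ValueError(f"participant {pid}: matrix must be ({n} x n_voxels)")
            if not np.all(np.isfinite(mat)):
                raise ValueError(f"participant {pid}: non-finite responses")
            self.responses[pid] = mat

    @property
    def participants(self) -> list[str]:
        return list(self.responses)

    def experiment_ids(self) -> list[str]:
        out: list[str] = []
        for sid in self.sentence_ids:
            e = self.experiment_of[sid]
            if e not in out:
                out.append(e)
        return out

    def rows(self, pid: str, sentence_ids: Sequence[str]) -> np.ndarray:
        index = {sid: i for i, sid in enumerate(self.sentence_ids)}
        return self.responses[pid][[index[s] for s in sentence_ids]]

    def to_hdf5(self, path: str | Path) -> None:
        """Write responses (ground truth, if any, is not serialized)."""
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("sentence_ids", data=np.array(self.sentence_ids, dtype="S"))
            fh.create_dataset(
                "experiment_of",
                data=np.array([self.experiment_of[s] for s in self.sentence_ids], dtype="S"),
            )
            grp = fh.create_group("responses")
            for pid, mat in self.responses.items():
                grp.create_dataset(pid, data=mat)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "BrainDataset":
        import h5py

        with h5py.File(path, "r") as fh:
            ids = [s.decode() for s in fh["sentence_ids"][()]]
            exps = [s.decode() for s in fh["experiment_of"][()]]
            responses = {pid: fh["responses"][pid][()] for pid in fh["responses"]}
        return cls(ids, dict(zip(ids, exps)), responses)


@dataclass(frozen=True)
class SplitScheme:
    """Cross-validation scheme: k folds over sentences or whole passages."""

    k: int = 5
    unit: str = "sentence"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("need at least 2 folds")
        if self.unit not in ("sentence", "passage"):
            raise ValueError("unit must be 'sentence' or 'passage'")


@dataclass(frozen=True)
class Design:
    """Computational experimental design cell (2 x 2 factorial)."""

    train_source: str = "intact"
    context_mode: str = "contextualized"

    def __post_init__(self) -> None:
        if self.train_source not in ("intact", "perturbed"):
            raise ValueError("train_source must be 'intact' or 'perturbed'")
        if self.context_mode not in ("contextualized", "decontextualized"):
            raise ValueError("bad context_mode")

    @property
    def name(self) -> str:
        t = "TrainIntact" if self.train_source == "intact" else "TrainPerturbed"
        c = "Contextualized" if self.context_mode == "contextualized" else "Decontextualized"
        return f"{t}-TestPerturbed_{c}"


def make_folds(
    sentence_ids: Sequence[str],
    passage_of: Mapping[str, str],
    scheme: SplitScheme,
) -> np.ndarray:
    """Random fold assignment (one integer in [0, k) per sentence).

    With ``unit="passage"`` whole passages are assigned to folds, so no
    passage is split across folds.  Fold sizes are balanced within one unit.
    """
    rng = np.random.default_rng(scheme.seed)
    n = len(sentence_ids)
    if scheme.unit == "sentence":
        if scheme.k > n:
            raise ValueError("more folds than sentences")
        order = rng.permutation(n)
        assignment = np.empty(n, dtype=int)
        for fold, chunk in enumerate(np.array_split(order, scheme.k)):
            assignment[chunk] = fold
        return assignment
    passages = []
    for sid in sentence_ids:
        p = passage_of[sid]
        if p not in passages:
            passages.append(p)
    if scheme.k > len(passages):
        raise ValueError("more folds than passages")
    order = rng.permutation(len(passages))
    passage_fold = {}
    for fold, chunk in enumerate(np.array_split(order, scheme.k)):
        for idx in chunk:
            passage_fold[passages[int(idx)]] = fold
    return np.array([passage_fold[passage_of[sid]] for sid in sentence_ids], dtype=int)


def fit_linear_map(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Per-voxel least squares with intercept.

    Returns weights of shape (dim + 1, n_voxels); the first row is the
    intercept.  Rank-deficient problems get the minimum-norm solution.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y row counts differ")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    Xa = np.column_stack([np.ones(X.shape[0]), X])
    W, *_ = np.linalg.lstsq(Xa, Y, rcond=None)
    return W


def predict(W: np.ndarray, X: np.ndarray) -> np.ndarray:
    Xa = np.column_stack([np.ones(np.asarray(X).shape[0]), X])
    return Xa @ W


def score_heldout(W: np.ndarray, X_test: np.ndarray, Y_test: np.ndarray) -> np.ndarray:
    """Per-voxel Pearson r between predicted and measured responses.

    Voxels with zero-variance predictions or targets score 0 (flagged via a
    warning rather than dropped, keeping shapes stable).  Requires at least
    3 test rows.
    """
    Y_test = np.asarray(Y_test, dtype=float)
    if Y_test.shape[0] < 3:
        raise ValueError("need at least 3 test rows for a meaningful correlation")
    P = predict(W, X_test)
    if P.shape != Y_test.shape:
        raise ValueError("prediction/target shape mismatch")
    Pc = P - P.mean(axis=0)
    Yc = Y_test - Y_test.mean(axis=0)
    sp = np.sqrt((Pc**2).sum(axis=0))
    sy = np.sqrt((Yc**2).sum(axis=0))
    denom = sp * sy
    bad = denom == 0
    denom[bad] = 1.0
    r = (Pc * Yc).sum(axis=0) / denom
    if np.any(bad):
        warnings.warn(f"{int(bad.sum())} voxel(s) had zero-variance prediction or target; r set to 0")
        r[bad] = 0.0
    return np.clip(r, -1.0, 1.0)


def apply_test_shuffle(
    condition: str,
    test_ids: Sequence[str],
    grouping: Mapping[str, str] | None,
    rng: np.random.Generator,
) -> tuple[dict, float]:
    """Constrained within-fold reassignment for the replacement conditions.

    RandSent deranges the whole test fold; the FromPassage/FromTopic
    variants derange within the given grouping, leaving singletons in place.
    Returns (sentence id -> source sentence id, unshuffled fraction).
    """
    if condition not in _SHUFFLED_CONDITIONS:
        raise ValueError(f"{condition} is not a test-shuffle condition")
    ids = list(test_ids)
    if condition == "RandSent":
        if len(ids) < 2:
            return {i: i for i in ids}, 1.0
        return derange(ids, rng), 0.0
    if grouping is None:
        raise ValueError("grouped shuffle needs a grouping")
    return group_constrained_shuffle(ids, grouping, rng)


@dataclass
class ScoreTable:
    """Tidy predictivity scores: condition x layer x participant x experiment.

    Layers are 1-based in the table.  Per-fold per-voxel detail is kept in
    ``detail`` keyed by (experiment, participant, layer) with arrays of
    shape (n_folds, n_voxels).
    """

    data: pd.DataFrame
    detail: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    REQUIRED = ("condition", "layer", "participant", "experiment", "score")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"score table missing columns: {missing}")
        if not np.all(np.isfinite(self.data["score"])):
            raise ValueError("scores must be finite")

    def participant_scores(self, condition: str | None = None) -> pd.DataFrame:
        """Per-participant scores averaged across experiments
        (condition, layer, participant, score)."""
        df = self.data
        if condition is not None:
            df = df[df["condition"] == condition]
        return (
            df.groupby(["condition", "layer", "participant"], as_index=False)["score"]
            .mean()
        )

    def layer_medians(self, condition: str) -> pd.Series:
        """Across-participant median score per layer (1-based index)."""
        ps = self.participant_scores(condition)
        return ps.groupby("layer")["score"].median()

    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.data["condition"]))

    @classmethod
    def concat(cls, tables: Sequence["ScoreTable"]) -> "ScoreTable":
        data = pd.concat([t.data for t in tables], ignore_index=True)
        detail: dict = {}
        meta: dict = {}
        for t in tables:
            detail.update({(t.data["condition"].iloc[0], *k): v for k, v in t.detail.items()})
            meta.update(t.meta)
        return cls(data, detail, meta)

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        self.data.to_csv(path, index=False)
        if sidecar and self.meta:
            Path(path).with_suffix(".meta.json").write_text(json.dumps(self.meta, indent=2))

    def detail_to_hdf5(self, path: str | Path) -> None:
        """Per-fold per-voxel correlations, one dataset per score-table key."""
        import h5py

        with h5py.File(path, "w") as fh:
            for key, arr in self.detail.items():
                fh.create_dataset("/".join(str(k) for k in key), data=np.asarray(arr))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScoreTable":
        meta_path = Path(path).with_suffix(".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(pd.read_csv(path), meta=meta)


def select_best_layer(
    table: ScoreTable,
    policy: str = "per_condition",
) -> dict[str, tuple[int, float]]:
    """Best layer (1-based) and its across-participant median per condition.

    ``per_condition`` takes each condition's own argmax over layers;
    ``fixed_on_original`` applies the Original condition's argmax layer to
    every condition.  Ties break toward the deeper layer.
    """
    if policy not in ("per_condition", "fixed_on_original"):
        raise ValueError(f"unknown policy: {policy}")

    def argmax_deep(series: pd.Series) -> int:
        best = series.max()
        return int(max(layer for layer, v in series.items() if v == best))

    out: dict[str, tuple[int, float]] = {}
    if policy == "fixed_on_original":
        if "Original" not in table.conditions():
            raise ValueError("fixed_on_original needs an Original condition")
        fixed = argmax_deep(table.layer_medians("Original"))
    for cond in table.conditions():
        medians = table.layer_medians(cond)
        layer = argmax_deep(medians) if policy == "per_condition" else fixed
        out[cond] = (layer, float(medians.loc[layer]))
    return out


class EncodingModel:
    """Voxelwise linear encoding benchmark for one perturbation condition.

    Parameters
    ----------
    stimuli : the stimulus set (provides experiment/passage/topic structure).
    brain : responses aligned to ``stimuli``'s sentence order.
    stores : representation stores keyed by condition name; must contain the
        target condition and, for the train-on-intact design, "Original".
    condition : the perturbation condition being benchmarked.
    design : train-source x contextualization cell.
    scheme : cross-validation scheme.
    """

    def __init__(
        self,
        stimuli: StimulusSet,
        brain: BrainDataset,
        stores: Mapping[str, RepresentationStore],
        condition: str,
        design: Design = Design(),
        scheme: SplitScheme = SplitScheme(),
    ) -> None:
        if condition not in CONDITION_CATEGORY:
            raise ValueError(f"unknown condition: {condition}")
        if list(brain.sentence_ids) != list(stimuli.sentence_ids):
            raise ValueError("brain rows are not aligned with the stimulus set")
        self.stimuli = stimuli
        self.brain = brain
        self.stores = dict(stores)
        self.condition = condition
        self.design = design
        self.scheme = scheme
        self._test_store_name = condition
        self._train_store_name = "Original" if design.train_source == "intact" else condition
        self._uses_fold_shuffle = (
            design.train_source == "intact" and condition in _SHUFFLED_CONDITIONS
        )
        if self._uses_fold_shuffle:
            # replacement happens inside each test fold on Original reps
            self._test_store_name = "Original"
        for name in {self._train_store_name, self._test_store_name}:
            if name not in self.stores:
                raise ValueError(f"missing representation store: {name}")
            store = self.stores[name]
            if set(store.sentence_ids) < set(stimuli.sentence_ids):
                raise ValueError(f"store {name} does not cover the stimulus set")

    # ------------------------------------------------------------------
    def fit(self) -> "EncodingResults":
        train_store = self.stores[self._train_store_name]
        test_store = self.stores[self._test_store_name]
        n_layers = test_store.n_layers
        passage_of = self.stimuli.passage_of()
        topic_of = self.stimuli.topic_of()
        rows: list[dict] = []
        detail: dict = {}
        fractions: dict = {}
        for eid in self.stimuli.experiment_ids():
            exp_ids = [s.id for s in self.stimuli if s.experiment_id == eid]
            scheme = replace(self.scheme, seed=seed_for(self.scheme.seed, "folds", eid))
            folds = make_folds(exp_ids, passage_of, scheme)
            participants = [
                pid for pid, mat in self.brain.responses.items()
            ]
            # concatenate participants' voxels; X is shared across them
            voxel_slices: dict[str, slice] = {}
            mats = []
            offset = 0
            for pid in participants:
                mat = self.brain.rows(pid, exp_ids)
                voxel_slices[pid] = slice(offset, offset + mat.shape[1])
                offset += mat.shape[1]
                mats.append(mat)
            Y_all = np.hstack(mats)
            per_fold_r = np.zeros((self.scheme.k, n_layers, Y_all.shape[1]))
            for fold in range(self.scheme.k):
                train_ids = [sid for sid, f in zip(exp_ids, folds) if f != fold]
                test_ids = [sid for sid, f in zip(exp_ids, folds) if f == fold]
                source_ids = list(test_ids)
                if self._uses_fold_shuffle:
                    rng = np.random.default_rng(
                        seed_for(self.scheme.seed, "test-shuffle", self.condition, eid, fold)
                    )
                    grouping = None
                    if self.condition == "RandSentFromPassage":
                        grouping = passage_of
                    elif self.condition == "RandSentFromTopic":
                        grouping = topic_of
                    mapping, frac = apply_test_shuffle(
                        self.condition, test_ids, grouping, rng
                    )
                    source_ids = [mapping[sid] for sid in test_ids]
                    fractions[(eid, fold)] = frac
                tr_rows = {sid: i for i, sid in enumerate(exp_ids)}
                Y_train = Y_all[[tr_rows[s] for s in train_ids]]
                Y_test = Y_all[[tr_rows[s] for s in test_ids]]
                for layer in range(n_layers):
                    X_train = train_store.rows(train_ids, layer)
                    X_test = test_store.rows(source_ids, layer)
                    W = fit_linear_map(X_train, Y_train)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        per_fold_r[fold, layer] = score_heldout(W, X_test, Y_test)
            voxel_mean_r = per_fold_r.mean(axis=0)  # (n_layers, total voxels)
            for pid in participants:
                sl = voxel_slices[pid]
                for layer in range(n_layers):
                    detail[(eid, pid, layer + 1)] = per_fold_r[:, layer, sl]
                    rows.append(
                        {
                            "condition": self.condition,
                            "layer": layer + 1,
                            "participant": pid,
                            "experiment": eid,
                            "score": float(np.median(voxel_mean_r[layer, sl])),
                        }
                    )
        table = ScoreTable(
            pd.DataFrame(rows),
            detail=detail,
            meta={
                "condition": self.condition,
                "design": self.design.name,
                "scheme": {"k": self.scheme.k, "unit": self.scheme.unit, "seed": self.scheme.seed},
                "unshuffled_fractions": {f"{e}/fold{f}": v for (e, f), v in fractions.items()},
            },
        )
        return EncodingResults(self, table, fractions)


class EncodingResults:
    """Fitted benchmark scores for one condition under one design."""

    def __init__(self, model: EncodingModel, scores: ScoreTable, fractions: dict) -> None:
        self.model = model
        self.scores = scores
        self.unshuffled_fractions = fractions

    @property
    def condition(self) -> str:
        return self.model.condition

    def participant_scores(self) -> pd.DataFrame:
        return self.scores.participant_scores(self.condition)

    def layer_medians(self) -> pd.Series:
        return self.scores.layer_medians(self.condition)

    def best_layer(self) -> tuple[int, float]:
        return select_best_layer(self.scores)[self.condition]

    def mean_unshuffled_fraction(self) -> float | None:
        if not self.unshuffled_fractions:
            return None
        return float(np.mean(list(self.unshuffled_fractions.values())))

    def summary(self) -> str:
        layer, score = self.best_layer()
        lines = [
            "Encoding benchmark results",
            "==========================",
            f"condition:      {self.condition}",
            f"design:         {self.model.design.name}",
            f"cv:             {self.model.scheme.k}-fold by {self.model.scheme.unit}",
            f"participants:   {len(self.model.brain.participants)}",
            f"layers:         {self.scores.data['layer'].max()}",
            f"best layer:     {layer} (median participant score {score:.4f})",
        ]
        frac = self.mean_unshuffled_fraction()
        if frac is not None:
            lines.append(f"mean unshuffled fraction: {frac:.4f}")
        lines.append("")
        lines.append("median score per layer:")
        for layer_idx, v in self.layer_medians().items():
            lines.append(f"  layer {layer_idx:>3d}: {v:+.4f}")
        return "\n".join(lines)

    def plot_layers(self, ax=None):
        """Median participant score per layer (matplotlib)."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3))
        med = self.layer_medians()
        ax.plot(med.index, med.values, marker="o")
        ax.set_xlabel("layer")
        ax.set_ylabel("median participant score (r)")
        ax.set_title(self.condition)
        return ax


def mean_unshuffled_fraction(
    stimuli: StimulusSet,
    condition: str,
    n_seeds: int = 100,
    k: int = 5,
    master_seed: int = 0,
) -> float:
    """Mean fraction of test-fold sentences the constrained shuffle leaves
    in place, over random k-fold assignments.

    For each seed, each experiment's sentences are randomly partitioned into
    k folds; within each test fold the replacement condition's constrained
    shuffle is applied and the unmoved fraction recorded.  Fractions are
    averaged over folds and experiments weighted by test-fold size, then
    over seeds.  Sentence replacement groups smaller than the fold leave
    singletons, which is why the within-passage variant leaves roughly half
    the test sentences unshuffled under five folds.
    """
    passage_of = stimuli.passage_of()
    topic_of = stimuli.topic_of()
    grouping = {
        "RandSentFromPassage": passage_of,
        "RandSentFromTopic": topic_of,
        "RandSent": None,
    }[condition]
    per_seed = []
    for s in range(n_seeds):
        unmoved = 0.0
        total = 0
        for eid in stimuli.experiment_ids():
            ids = [x.id for x in stimuli if x.experiment_id == eid]
            folds = make_folds(
                ids, passage_of, SplitScheme(k, "sentence", seed_for(master_seed, s, "folds", eid))
            )
            for fold in range(k):
                test_ids = [sid for sid, f in zip(ids, folds) if f == fold]
                rng = np.random.default_rng(seed_for(master_seed, s, "shuffle", eid, fold))
                _, frac = apply_test_shuffle(condition, test_ids, grouping, rng)
                unmoved += frac * len(test_ids)
                total += len(test_ids)
        per_seed.append(unmoved / total)
    return float(np.mean(per_seed))


def run_benchmark(
    condition: str,
    design: Design,
    scheme: SplitScheme,
    stores: Mapping[str, RepresentationStore],
    brain: BrainDataset,
    stimuli: StimulusSet,
) -> ScoreTable:
    """Functional wrapper: build an :class:`EncodingModel`, fit, return scores."""
    return EncodingModel(stimuli, brain, stores, condition, design, scheme).fit().scores
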