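"""End-to-end orchestration: simulate -> perturb -> embed -> encode -> analyze.

A :class:`RunConfig` fixes every input (structure, provider geometry,
conditions, design, CV scheme) and a single master seed; all stage-level
randomness is derived hierarchically from that seed, so a rerun with the
same config is bit-identical and adding a condition never perturbs the
outputs of the others.  Artifacts are plain files: JSON-lines stimuli, TSV
count tables, HDF5 representation stores, CSV score/similarity/surprisal
tables, a JSON ceiling estimate, and PNG figures.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path


from . import analyze
from .ceiling import NoiseCeilingModel
from .corpus import write_stimuli
from .encode import (
    Design,
    EncodingModel,
    ScoreTable,
    SplitScheme,
    select_best_layer,
)
from .perturb import CONDITIONS, PmiConfig, perturb_stimulus_set, seed_for
from .represent import (
    RepresentationStore,
    SyntheticEmbeddingProvider,
    encode_condition,
    encode_content_tokens,
)
from .synthdata import (
    BrainSpec,
    SynthConfig,
    gen_bigram_lm,
    gen_brain,
    gen_counts,
    gen_paraphrases,
    gen_stimulus_set,
    surprisal_noise,
)

__all__ = ["RunConfig", "run_pipeline", "DEFAULT_CONDITIONS"]

#: The 18 conditions of the main analysis (the two extra length controls are
#: available but off by default, as in the main condition set).
DEFAULT_CONDITIONS = tuple(
    c for c in CONDITIONS if c not in ("RandN", "LengthControl")
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    train_source: str = "intact"
    context_mode: str = "contextualized"
    summary_mode: str = "mean_token"
    k_folds: int = 5
    split_unit: str = "sentence"
    n_layers: int = 6
    dim: int = 32
    context_weight: float = 0.3
    positional_weight: float = 0.1
    #: strength of surprisal-dependent representation degradation in the
    #: synthetic provider (0 disables); the planted link between a string's
    #: predictability and the quality of its representations.
    ood_noise_weight: float = 2.0
    synth: SynthConfig = field(default_factory=SynthConfig)
    counts_sentences: int = 3000
    #: what the synthetic brain encodes: "content_words" plants the voxel
    #: readout on mean content-word token vectors with a content-restricted
    #: context average (a meaning-driven language network, the regime the
    #: directional predictions assume); "original_summary" plants it on the
    #: Original condition's summary vectors instead.
    brain_reference: str = "content_words"
    do_ceiling: bool = True
    do_figures: bool = True
    save_representations: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth_raw = raw.pop("synth", None)
        kwargs = dict(raw)
        if "conditions" in kwargs:
            kwargs["conditions"] = tuple(kwargs["conditions"])
        if synth_raw is not None:
            brain = BrainSpec(**synth_raw.pop("brain", {}))
            kwargs["synth"] = SynthConfig(brain=brain, **synth_raw)
        return cls(**kwargs)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, tuple):
                return list(o)
            raise TypeError(type(o))

        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline and return the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    synth = dataclasses.replace(config.synth, seed=seed_for(seed, "synth"))

    # --- simulate ------------------------------------------------------
    stimuli = gen_stimulus_set(synth)
    write_stimuli(stimuli, out / "stimuli.jsonl")
    counts = gen_counts(synth, n_sentences=config.counts_sentences)
    counts.to_tsv(out / "counts.tsv")
    paraphrases = gen_paraphrases(stimuli, synth)
    lm = gen_bigram_lm(counts)

    # --- perturb -------------------------------------------------------
    perturbed = {
        cond: perturb_stimulus_set(
            stimuli, cond, seed_for(seed, "perturb"),
            counts=counts, pmi_cfg=PmiConfig(), paraphrases=paraphrases,
        )
        for cond in config.conditions
    }

    # --- embed ---------------------------------------------------------
    provider_kwargs = dict(
        seed=seed_for(seed, "provider"),
        n_layers=config.n_layers,
        dim=config.dim,
        context_weight=config.context_weight,
        positional_weight=config.positional_weight,
    )
    token_noise = (
        surprisal_noise(lm, weight=config.ood_noise_weight)
        if config.ood_noise_weight > 0
        else None
    )
    provider = SyntheticEmbeddingProvider(token_noise=token_noise, **provider_kwargs)
    stores: dict[str, RepresentationStore] = {}
    for cond in config.conditions:
        stores[cond] = encode_condition(
            stimuli, perturbed[cond] if cond != "Original" else None,
            provider, config.context_mode, config.summary_mode, condition=cond,
        )
        if config.save_representations:
            (out / "representations").mkdir(exist_ok=True)
            stores[cond].to_hdf5(out / "representations" / f"{cond}.h5")

    # --- brain ---------------------------------------------------------
    if config.brain_reference == "content_words":
        # the synthetic language network encodes intact (non-degraded)
        # content-word representations in full-sentence time
        clean_provider = SyntheticEmbeddingProvider(**provider_kwargs)
        reference = encode_content_tokens(stimuli, clean_provider, config.context_mode)
    elif config.brain_reference == "original_summary":
        reference = stores["Original"]
    else:
        raise ValueError(f"unknown brain_reference: {config.brain_reference}")
    brain = gen_brain(stimuli, reference, synth)
    brain.to_hdf5(out / "brain.h5")

    # --- encode --------------------------------------------------------
    design = Design(config.train_source, config.context_mode)
    scheme = SplitScheme(config.k_folds, config.split_unit, seed_for(seed, "folds"))
    tables = []
    for cond in config.conditions:
        model = EncodingModel(stimuli, brain, stores, cond, design, scheme)
        tables.append(model.fit().scores)
    scores = ScoreTable.concat(tables)
    scores.meta.update({"config_hash": config.config_hash(), "seed": seed})
    scores.to_csv(out / "scores.csv")

    # --- ceiling -------------------------------------------------------
    if config.do_ceiling and len(brain.participants) >= 3:
        ceiling = NoiseCeilingModel(brain, scheme=scheme).fit(seed=seed_for(seed, "ceiling"))
        ceiling.to_json(out / "ceiling.json")

    # --- analyze -------------------------------------------------------
    sim = analyze.similarity_table(stores)
    sim.to_csv(out / "similarity.csv", index=False)
    sim_r, sim_points = analyze.similarity_predictivity_correlation(sim, scores)
    sim_points.to_csv(out / "similarity_predictivity.csv", index=False)
    sup = analyze.surprisal_table(perturbed, lm)
    sup.to_csv(out / "surprisal.csv", index=False)
    try:
        sup_r, sup_points = analyze.surprisal_predictivity_correlation(sup, scores)
        sup_points.to_csv(out / "surprisal_predictivity.csv", index=False)
    except ValueError:
        sup_r = None
    best = select_best_layer(scores)
    participants = {
        cond: scores.participant_scores(cond)
        .query(f"layer == {best[cond][0]}")
        .sort_values("participant")["score"]
        .to_numpy()
        .tolist()
        for cond in config.conditions
    }
    contrasts = analyze.dependent_ttests(
        participants,
        pairs=[(c, "Original") for c in config.conditions if c != "Original"],
        family="vs_original",
    )
    contrasts.comparisons.to_csv(out / "stats.csv", index=False)

    report = {
        "config_hash": config.config_hash(),
        "seed": seed,
        "design": design.name,
        "n_sentences": len(stimuli),
        "n_conditions": len(config.conditions),
        "n_layers": config.n_layers,
        "best_layer": {c: {"layer": l, "score": s} for c, (l, s) in best.items()},
        "similarity_predictivity_r": sim_r,
        "similarity_points": int(len(sim_points)),
        "surprisal_predictivity_r": sup_r,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))

    if config.do_figures:
        analyze.plot_condition_scores(scores, out / "predictivity.png")
    return out
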