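"""Satellite stimulus structure, learning/test schedules, and synthetic
pre/post-nap behavioral data with plantable cueing effects.

The stimulus space is the classic "satellite" category-learning design:
three categories of five novel objects, five visual feature slots each. One
exemplar per category is the prototype (all category-typical features); every
other exemplar carries four shared features and exactly one globally unique
feature. Memory is probed with a six-alternative feature-inference test, so
chance is 1/6.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

N_OPTIONS = 6
CHANCE_LEVEL = 1.0 / N_OPTIONS

CATEGORY_NAMES = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta")


# ---------------------------------------------------------------------------
# Stimuli
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Exemplar:
    item_id: str
    category: str
    features: tuple[str, ...]      # feature id per slot
    unique_slot: int | None        # None -> prototype

    @property
    def is_prototype(self) -> bool:
        return self.unique_slot is None

    def feature_type(self, slot: int) -> str:
        return "unique" if slot == self.unique_slot else "shared"

    @property
    def shared_slots(self) -> tuple[int, ...]:
        return tuple(s for s in range(len(self.features))
                     if s != self.unique_slot)


@dataclass(frozen=True)
class StimulusSet:
    exemplars: tuple[Exemplar, ...]
    n_features: int = 5

    @property
    def categories(self) -> tuple[str, ...]:
        seen: list[str] = []
        for e in self.exemplars:
            if e.category not in seen:
                seen.append(e.category)
        return tuple(seen)

    def items_by_category(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for e in self.exemplars:
            out.setdefault(e.category, []).append(e.item_id)
        return out

    def of_category(self, category: str) -> list[Exemplar]:
        return [e for e in self.exemplars if e.category == category]

    @property
    def prototypes(self) -> list[Exemplar]:
        return [e for e in self.exemplars if e.is_prototype]

    @property
    def non_prototypes(self) -> list[Exemplar]:
        return [e for e in self.exemplars if not e.is_prototype]

    def exemplar(self, item_id: str) -> Exemplar:
        for e in self.exemplars:
            if e.item_id == item_id:
                return e
        raise KeyError(item_id)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"n_features": self.n_features,
             "exemplars": [asdict(e) for e in self.exemplars]}, indent=1))


def build_stimuli(seed: int | None = None, n_categories: int = 3,
                  n_exemplars: int = 5, n_features: int = 5) -> StimulusSet:
    """Random satellite set obeying the category structure: one prototype per
    category; every other exemplar has one unique feature in a random slot;
    unique feature ids are globally distinct."""
    rng = np.random.default_rng(seed)
    exemplars: list[Exemplar] = []
    uniq_counter = 0
    for ci in range(n_categories):
        cat = CATEGORY_NAMES[ci]
        proto_feats = tuple(f"{cat}_s{slot}" for slot in range(n_features))
        proto_idx = int(rng.integers(n_exemplars))
        for xi in range(n_exemplars):
            item_id = f"{cat}-{xi + 1}"
            if xi == proto_idx:
                exemplars.append(Exemplar(item_id, cat, proto_feats, None))
            else:
                slot = int(rng.integers(n_features))
                feats = list(proto_feats)
                feats[slot] = f"u{uniq_counter}"
                uniq_counter += 1
                exemplars.append(Exemplar(item_id, cat, tuple(feats), slot))
    return StimulusSet(tuple(exemplars), n_features=n_features)


# ---------------------------------------------------------------------------
# Learning schedule
# ---------------------------------------------------------------------------

BLOCK_LENGTH = 45
UNIQUE_QUERY_WEIGHT = 2.21   # unique:shared sampling-weight ratio


@dataclass(frozen=True)
class LearningTrial:
    item_id: str
    slot: int
    feature_type: str


def build_learning_schedule(stimuli: StimulusSet, seed: int | None = None,
                            n_blocks: int = 4,
                            unique_weight: float = UNIQUE_QUERY_WEIGHT
                            ) -> list[list[LearningTrial]]:
    """Learning blocks of 45 feature-inference trials.

    Each trial queries one feature slot of one satellite, drawn with unique
    slots weighted ``unique_weight`` : 1 relative to shared slots, so the
    realized unique:shared query ratio converges to 2.21 over many blocks.
    """
    rng = np.random.default_rng(seed)
    pool: list[tuple[str, int, str]] = []
    weights: list[float] = []
    for e in stimuli.exemplars:
        for slot in range(len(e.features)):
            ft = e.feature_type(slot)
            pool.append((e.item_id, slot, ft))
            weights.append(unique_weight if ft == "unique" else 1.0)
    w = np.asarray(weights) / np.sum(weights)
    blocks = []
    for _ in range(n_blocks):
        picks = rng.choice(len(pool), size=BLOCK_LENGTH, p=w)
        blocks.append([LearningTrial(*pool[i]) for i in picks])
    return blocks


def should_stop(block_accuracies: Sequence[float], elapsed_min: float,
                criterion: float = 0.66, fallback: float = 0.50,
                fallback_after_min: float = 60.0) -> bool:
    """Learning stopping rule: stop on a block at the accuracy criterion, or
    on a block at the fallback level once the time limit has elapsed. Pure
    function of the block accuracies and elapsed time."""
    if not block_accuracies:
        return False
    last = block_accuracies[-1]
    return last >= criterion or (elapsed_min >= fallback_after_min
                                 and last >= fallback)


# ---------------------------------------------------------------------------
# Test schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestTrial:
    item_id: str
    category: str
    slots: tuple[int, ...]            # 1 or 2 queried feature slots
    feature_types: tuple[str, ...]
    novel: bool = False


class SchedulingError(RuntimeError):
    """The no-adjacent-repeat constraint could not be satisfied."""


def build_test_schedule(stimuli: StimulusSet, n_novel: int = 3,
                        seed: int | None = None) -> list[TestTrial]:
    """Pre/post-nap test trials.

    Per non-prototype satellite: three trials — (two shared), (shared then
    unique), (unique then shared) — so its unique feature is queried twice
    and each of its four shared features exactly once. Per prototype: two
    trials of two different shared features (four distinct shared features).
    Novel satellites (one per category by default) are queried on one shared
    feature. No satellite appears on consecutive trials.
    """
    rng = np.random.default_rng(seed)
    trials: list[TestTrial] = []
    for e in stimuli.non_prototypes:
        sh = list(e.shared_slots)
        rng.shuffle(sh)
        u = e.unique_slot
        trials.append(TestTrial(e.item_id, e.category, (sh[0], sh[1]),
                                ("shared", "shared")))
        trials.append(TestTrial(e.item_id, e.category, (sh[2], u),
                                ("shared", "unique")))
        trials.append(TestTrial(e.item_id, e.category, (u, sh[3]),
                                ("unique", "shared")))
    for e in stimuli.prototypes:
        sl = list(range(len(e.features)))
        rng.shuffle(sl)
        trials.append(TestTrial(e.item_id, e.category, (sl[0], sl[1]),
                                ("shared", "shared")))
        trials.append(TestTrial(e.item_id, e.category, (sl[2], sl[3]),
                                ("shared", "shared")))
    cats = stimuli.categories
    for k in range(n_novel):
        cat = cats[k % len(cats)]
        slot = int(rng.integers(stimuli.n_features))
        trials.append(TestTrial(f"novel-{cat}-{k + 1}", cat, (slot,),
                                ("shared",), novel=True))
    return _no_adjacent_shuffle(trials, rng)


def _no_adjacent_shuffle(trials: list[TestTrial],
                         rng: np.random.Generator,
                         max_tries: int = 200) -> list[TestTrial]:
    order = list(trials)
    for _ in range(max_tries):
        rng.shuffle(order)
        ok = True
        for i in range(1, len(order)):
            if order[i].item_id == order[i - 1].item_id:
                # try to repair by swapping with a compatible later trial
                fixed = False
                for j in range(i + 1, len(order)):
                    if (order[j].item_id != order[i - 1].item_id
                            and (i + 1 >= len(order)
                                 or order[j].item_id != order[i + 1].item_id)):
                        order[i], order[j] = order[j], order[i]
                        fixed = True
                        break
                if not fixed:
                    ok = False
                    break
        if ok:
            return order
    raise SchedulingError("could not order trials without adjacent repeats")


def query_counts(stimuli: StimulusSet) -> dict[tuple[str, str], int]:
    """Per (item, feature_type): number of test queries the schedule makes.

    Non-prototypes: unique queried 2x, shared features 4 x 1. Prototypes:
    4 shared queries. These counts set the binomial denominators of the
    simulated item-level accuracies.
    """
    out: dict[tuple[str, str], int] = {}
    for e in stimuli.exemplars:
        if e.is_prototype:
            out[(e.item_id, "shared")] = 4
        else:
            out[(e.item_id, "shared")] = 4
            out[(e.item_id, "unique")] = 2
    return out


# ---------------------------------------------------------------------------
# Behavioral data generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSpec:
    """Planted effect structure, in accuracy units (probability scale).

    Defaults reproduce the study conditions this package simulates: pre-nap
    accuracy ~0.79 (unique) / 0.47 (shared); a cueing x feature-type
    interaction of delta_unique + delta_shared = 0.17 split as +0.12 on
    unique and -0.05 on shared features of cued items; 0.6 of the cued-item
    effect spreading to uncued items of cued categories; a blocked/interleaved
    asymmetry whose mean over cued items is 1. ``drift`` absorbs all
    non-cueing pre-to-post change and is calibrated so the population pre and
    post means resemble the study's observed means.
    """

    base_accuracy: dict = field(default_factory=lambda: {
        "shared": 0.47, "unique": 0.79})
    drift: dict = field(default_factory=lambda: {
        "shared": 0.02, "unique": -0.14})
    delta_unique: float = 0.12
    delta_shared: float = 0.05
    spread_fraction: float = 0.6
    per_cue_increment: float = 0.0
    style_multiplier: dict = field(default_factory=lambda: {
        "blocked": 1.0, "interleaved": 1.0})
    seqpos_gradient: float = 0.0       # added effect per blocked position
    subject_sd: float = 0.06
    item_sd: float = 0.06
    tradeoff_slope: float = 0.0        # planted post-nap shared-on-unique slope
    confidence_noise_sd: float = 0.15
    mean_cues: float = 7.59
    sd_cues: float = 2.90
    cue_range: tuple[int, int] = (1, 18)
    # with binomial sampling off, accuracies equal the underlying
    # probabilities exactly (no observation noise)
    binomial_sampling: bool = True


BEHAVIOR_COLUMNS = [
    "subject", "item", "category", "feature_type", "is_novel",
    "cue_condition", "order_condition", "cue_stage", "times_cued",
    "sequence_position", "prenap_accuracy", "postnap_accuracy",
    "accuracy_difference", "prenap_confidence", "postnap_confidence",
    "confidence_difference", "theta_power", "spindle_power",
]


def simulate_behavior(stimuli: StimulusSet, effects: EffectSpec | None = None,
                      n_subjects: int = 34, seed: int | None = None,
                      cue_counts: dict[str, int] | None = None,
                      conditions: dict[str, str] | None = None) -> pd.DataFrame:
    """Synthetic item x feature-type accuracy table, pre and post nap.

    Per subject, categories are randomly assigned to interleaved / blocked /
    uncued (unless ``conditions`` maps category -> condition), one item per
    cued category is held out, and cue counts are drawn from a clipped normal
    matching the observed repetition distribution (unless ``cue_counts`` is
    given, e.g. from a realized session event log). Accuracies are binomial
    proportions over the test schedule's query counts; planted effects act on
    the underlying probabilities. Deterministic under ``seed``.
    """
    eff = effects or EffectSpec()
    rng = np.random.default_rng(seed)
    nq = query_counts(stimuli)
    cats = stimuli.categories
    rows: list[dict] = []
    for s in range(n_subjects):
        subj = f"s{s + 1:03d}"
        subj_eff = rng.normal(0.0, eff.subject_sd)
        if conditions is None:
            perm = rng.permutation(len(cats))
            cond_of = {cats[perm[0]]: "interleaved", cats[perm[1]]: "blocked"}
            for j in perm[2:]:
                cond_of[cats[j]] = "uncued"
        else:
            cond_of = dict(conditions)
        holdout: set[str] = set()
        for cat, cond in cond_of.items():
            if cond != "uncued":
                ids = [e.item_id for e in stimuli.of_category(cat)]
                holdout.add(ids[int(rng.integers(len(ids)))])
        # cue counts and blocked sequence positions
        times: dict[str, int] = {}
        seqpos: dict[str, float] = {}
        for cat, cond in cond_of.items():
            members = [e.item_id for e in stimuli.of_category(cat)]
            if cond == "uncued":
                for i in members:
                    times[i] = 0
                    seqpos[i] = 0.0
                continue
            cued_ids = [i for i in members if i not in holdout]
            for i in members:
                if i in holdout:
                    times[i] = 0
                    seqpos[i] = np.nan
                elif cue_counts is not None:
                    times[i] = int(cue_counts.get(i, 0))
                else:
                    lo, hi = eff.cue_range
                    times[i] = int(np.clip(round(rng.normal(
                        eff.mean_cues, eff.sd_cues)), lo, hi))
            if cond == "blocked":
                # all blocked items treated as fully cued; positions count
                # back from the nap end (4 = cued last)
                order = rng.permutation(len(cued_ids))
                n_pos = len(cued_ids)
                for rank, j in enumerate(order):
                    seqpos[cued_ids[j]] = float(n_pos - rank) if rank < 4 else np.nan
            else:
                for i in cued_ids:
                    seqpos[i] = np.nan

        for e in stimuli.exemplars:
            cond = cond_of[e.category]
            cued = cond != "uncued" and e.item_id not in holdout and times[e.item_id] > 0
            if cond == "uncued":
                cue_condition = "uncued"
            elif cued:
                cue_condition = "cued"
            else:
                cue_condition = "uncued_in_cued"
            cue_stage = (rng.choice(["N2", "N3", "both"]) if cued else "none")
            item_eff = rng.normal(0.0, eff.item_sd)
            fts = ["shared"] if e.is_prototype else ["shared", "unique"]
            obs: dict[str, dict] = {}
            for ft in fts:
                p_pre = float(np.clip(
                    eff.base_accuracy[ft] + subj_eff + item_eff, 0.0, 1.0))
                n = nq[(e.item_id, ft)]
                acc_pre = (rng.binomial(n, p_pre) / n if eff.binomial_sampling
                           else p_pre)
                obs[ft] = {"n": n, "p_pre": p_pre, "acc_pre": acc_pre}
            # planted post-nap probabilities
            for ft in fts:
                d = eff.drift[ft]
                if cue_condition in ("cued", "uncued_in_cued"):
                    delta = eff.delta_unique if ft == "unique" else -eff.delta_shared
                    if cue_condition == "uncued_in_cued":
                        delta *= eff.spread_fraction
                    else:
                        delta *= eff.style_multiplier.get(cond, 1.0)
                        if cond == "blocked" and not np.isnan(seqpos[e.item_id]):
                            delta += (np.sign(delta) * eff.seqpos_gradient
                                      * (seqpos[e.item_id] - 2.5))
                        delta += eff.per_cue_increment * (
                            times[e.item_id] - eff.mean_cues)
                    d = d + delta
                obs[ft]["p_post"] = float(np.clip(
                    obs[ft]["p_pre"] + d, 0.0, 1.0))
            # optional within-object tradeoff: shared post probability tied
            # to the observed unique accuracy so the planted observed-scale
            # slope equals eff.tradeoff_slope exactly in expectation
            if eff.tradeoff_slope != 0.0 and "unique" in obs:
                u_post_acc = (rng.binomial(2, obs["unique"]["p_post"]) / 2.0
                              if eff.binomial_sampling
                              else obs["unique"]["p_post"])
                obs["unique"]["acc_post"] = u_post_acc
                obs["shared"]["p_post"] = float(np.clip(
                    obs["shared"]["p_post"]
                    + eff.tradeoff_slope * (u_post_acc
                                            - eff.base_accuracy["unique"]),
                    0.0, 1.0))
            for ft in fts:
                o = obs[ft]
                if "acc_post" not in o:
                    o["acc_post"] = (rng.binomial(o["n"], o["p_post"]) / o["n"]
                                     if eff.binomial_sampling else o["p_post"])
                conf_pre = _confidence(o["p_pre"], rng, eff)
                conf_post = _confidence(o["p_post"], rng, eff)
                rows.append({
                    "subject": subj, "item": e.item_id, "category": e.category,
                    "feature_type": ft, "is_novel": False,
                    "cue_condition": cue_condition, "order_condition": cond,
                    "cue_stage": cue_stage, "times_cued": times[e.item_id],
                    "sequence_position": seqpos[e.item_id],
                    "prenap_accuracy": o["acc_pre"],
                    "postnap_accuracy": o["acc_post"],
                    "accuracy_difference": o["acc_post"] - o["acc_pre"],
                    "prenap_confidence": conf_pre,
                    "postnap_confidence": conf_post,
                    "confidence_difference": conf_post - conf_pre,
                    "theta_power": rng.normal(0.0, 1.0) if cued else np.nan,
                    "spindle_power": rng.normal(0.0, 1.0) if cued else np.nan,
                })
        # novel satellites: one per category, shared features only
        for cat in cats:
            cond = cond_of[cat]
            cat_times = [times[e.item_id] for e in stimuli.of_category(cat)]
            p_pre = float(np.clip(0.27 + subj_eff, 0.0, 1.0))
            acc_pre = rng.binomial(2, p_pre) / 2.0
            acc_post = rng.binomial(2, float(np.clip(p_pre - 0.02, 0, 1))) / 2.0
            rows.append({
                "subject": subj, "item": f"novel-{cat}", "category": cat,
                "feature_type": "shared", "is_novel": True,
                "cue_condition": "uncued" if cond == "uncued" else "cued",
                "order_condition": cond, "cue_stage": "none",
                "times_cued": int(np.sum(cat_times)),
                "sequence_position": np.nan,
                "prenap_accuracy": acc_pre, "postnap_accuracy": acc_post,
                "accuracy_difference": acc_post - acc_pre,
                "prenap_confidence": _confidence(p_pre, rng, eff),
                "postnap_confidence": _confidence(p_pre - 0.02, rng, eff),
                "confidence_difference": 0.0,
                "theta_power": np.nan, "spindle_power": np.nan,
            })
    df = pd.DataFrame(rows, columns=BEHAVIOR_COLUMNS)
    df["confidence_difference"] = (df["postnap_confidence"]
                                   - df["prenap_confidence"])
    return df


def _confidence(p: float, rng: np.random.Generator, eff: EffectSpec) -> float:
    """Noisy monotone transform of accuracy probability onto a 1-5 scale."""
    x = np.clip(p + rng.normal(0.0, eff.confidence_noise_sd), 0.0, 1.0)
    return float(np.round(1.0 + 4.0 * x))
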