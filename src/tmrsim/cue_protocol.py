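"""Cue planning and real-time gating for closed-loop memory reactivation.

The protocol follows the study design this package simulates: of three (or
more) stimulus categories, one is cued with its items interleaved, one with
its items blocked (all repetitions of an item consecutive), and the rest are
left uncued; one randomly chosen exemplar per cued category is additionally
held out. Cues are delivered only in N2/N3 sleep, only at a detected
slow-oscillation up-state, at least 2.5 s after the last detected spindle,
at least 8 s after the previous cue, and only after the sleeper has been in
N2 for three minutes. "No sound" (sham) slots are spaced through the cue list
and must satisfy exactly the same gate, so they are a matched control.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .online_detect import DetectorConfig, SODetector, SpindleDetector, CausalBandpass
from .synth_eeg import SyntheticRecording, stream

SHAM = "SHAM"


class Decision(Enum):
    DELIVER = "DELIVER"
    SHAM_MARK = "SHAM_MARK"
    WITHHOLD = "WITHHOLD"


@dataclass(frozen=True)
class ProtocolConfig:
    """Gating thresholds and plan-construction settings (durations in s)."""

    refractory: float = 2.5        # min gap since last detected spindle
    cue_lockout: float = 8.0       # pause after any delivered cue or sham
    arm_after_n2: float = 180.0    # N2 time required before the first cue
    allowed_stages: tuple[str, ...] = ("N2", "N3")
    sham_every_k: int = 6          # one sham slot after every k sound slots
    planned_reps_per_item: int = 18
    arming_contiguous: bool = True  # wake/N1/REM resets the arming clock

    def __post_init__(self) -> None:
        for name in ("refractory", "cue_lockout", "arm_after_n2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sham_every_k < 1:
            raise ValueError("sham_every_k must be >= 1")


@dataclass(frozen=True)
class CueItem:
    item_id: str
    category: str
    condition: str  # "interleaved" | "blocked" | "uncued"


@dataclass
class CuePlan:
    """Condition assignment, holdouts, and the ordered slot sequence."""

    items: list[CueItem]
    holdout_ids: dict[str, str]          # cued category -> held-out item
    slot_sequence: list[str]             # item_id or SHAM
    planned_reps_per_item: int

    def condition_of(self, item_id: str) -> str:
        for it in self.items:
            if it.item_id == item_id:
                return it.condition
        raise KeyError(item_id)

    def category_of(self, item_id: str) -> str:
        for it in self.items:
            if it.item_id == item_id:
                return it.category
        raise KeyError(item_id)

    @property
    def cueable_ids(self) -> list[str]:
        held = set(self.holdout_ids.values())
        return [it.item_id for it in self.items
                if it.condition != "uncued" and it.item_id not in held]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "items": [asdict(i) for i in self.items],
            "holdout_ids": self.holdout_ids,
            "slot_sequence": self.slot_sequence,
            "planned_reps_per_item": self.planned_reps_per_item,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CuePlan":
        d = json.loads(Path(path).read_text())
        return cls(items=[CueItem(**i) for i in d["items"]],
                   holdout_ids=d["holdout_ids"],
                   slot_sequence=d["slot_sequence"],
                   planned_reps_per_item=d["planned_reps_per_item"])


def _as_category_map(stimulus_set) -> dict[str, list[str]]:
    if isinstance(stimulus_set, Mapping):
        return {k: list(v) for k, v in stimulus_set.items()}
    return stimulus_set.items_by_category()


def build_cue_plan(stimulus_set, seed: int | None = None,
                   config: ProtocolConfig | None = None) -> CuePlan:
    """Assign conditions to categories, choose holdouts, and order the slots.

    The interleaved category's items rotate round-robin; the blocked
    category's slots are grouped per item (all repetitions of one item before
    the next). The two cued categories are intermixed by alternating blocks of
    ``planned_reps_per_item`` slots, and a sham slot is inserted after every
    ``sham_every_k`` sound slots.
    """
    cfg = config or ProtocolConfig()
    by_cat = _as_category_map(stimulus_set)
    if len(by_cat) < 3:
        raise ValueError("need at least 3 categories")
    for cat, ids in by_cat.items():
        if len(ids) < 2:
            raise ValueError(f"category {cat!r} has fewer than 2 items")
    rng = np.random.default_rng(seed)
    cats = sorted(by_cat)
    order = rng.permutation(len(cats))
    interleaved_cat = cats[order[0]]
    blocked_cat = cats[order[1]]
    uncued_cats = [cats[i] for i in order[2:]]

    items: list[CueItem] = []
    for cat in cats:
        cond = ("interleaved" if cat == interleaved_cat
                else "blocked" if cat == blocked_cat else "uncued")
        items.extend(CueItem(i, cat, cond) for i in by_cat[cat])

    holdouts = {cat: by_cat[cat][int(rng.integers(len(by_cat[cat])))]
                for cat in (interleaved_cat, blocked_cat)}

    def cueable(cat: str) -> list[str]:
        ids = [i for i in by_cat[cat] if i != holdouts[cat]]
        return [ids[j] for j in rng.permutation(len(ids))]

    reps = cfg.planned_reps_per_item
    inter_ids = cueable(interleaved_cat)
    blocked_ids = cueable(blocked_cat)
    # round-robin stream for the interleaved category, chopped into blocks
    inter_stream = [inter_ids[j % len(inter_ids)]
                    for j in range(reps * len(inter_ids))]
    inter_chunks = [inter_stream[j:j + reps]
                    for j in range(0, len(inter_stream), reps)]
    blocked_chunks = [[i] * reps for i in blocked_ids]

    sounds: list[str] = []
    first_inter = bool(rng.integers(2))
    a, b = (inter_chunks, blocked_chunks) if first_inter else (blocked_chunks,
                                                               inter_chunks)
    for j in range(max(len(a), len(b))):
        if j < len(a):
            sounds.extend(a[j])
        if j < len(b):
            sounds.extend(b[j])

    slots: list[str] = []
    for j, s in enumerate(sounds, start=1):
        slots.append(s)
        if j % cfg.sham_every_k == 0:
            slots.append(SHAM)
    _ = uncued_cats  # uncued categories contribute no slots by definition
    return CuePlan(items=items, holdout_ids=holdouts, slot_sequence=slots,
                   planned_reps_per_item=reps)


def gate_cue(now: float, stage: str, so_trigger: bool,
             last_spindle_time: float, last_cue_time: float, armed: bool,
             config: ProtocolConfig, slot_is_sham: bool = False) -> Decision:
    """Pure gate: all protocol conditions must hold for a cue (or sham mark).

    ``last_spindle_time`` / ``last_cue_time`` may be ``-inf`` when no spindle
    or cue has occurred yet.
    """
    ok = (so_trigger
          and armed
          and stage in config.allowed_stages
          and now - last_spindle_time >= config.refractory
          and now - last_cue_time >= config.cue_lockout)
    if not ok:
        return Decision.WITHHOLD
    return Decision.SHAM_MARK if slot_is_sham else Decision.DELIVER


def arming_time(hypnogram, config: ProtocolConfig) -> float:
    """First time the arming criterion is met, or inf if never.

    The clock accumulates time in N2 (N3 keeps an already-started run alive);
    with ``arming_contiguous`` any other stage resets it.
    """
    acc = 0.0
    started = False
    for (t0, t1, stage) in hypnogram.segments():
        if stage == "N2" or (started and stage == "N3"):
            started = True
            need = config.arm_after_n2 - acc
            if t1 - t0 >= need:
                return t0 + need
            acc += t1 - t0
        else:
            if config.arming_contiguous:
                acc = 0.0
                started = False
    return np.inf


EVENT_LOG_COLUMNS = ["time", "item_id", "category", "condition",
                     "stage_at_event", "filtered_value_at_event",
                     "last_spindle_gap", "cue_index_within_item"]


def run_session(recording: SyntheticRecording,
                plan: CuePlan,
                config: ProtocolConfig | None = None,
                detector_config: DetectorConfig | None = None,
                seed: int | None = None,
                chunk_size: int = 128,
                channel: str = "Fz") -> pd.DataFrame:
    """Run the closed-loop engine over a recording in a single causal pass.

    Returns the realized event log: one row per delivered cue or sham mark
    with the gating quantities recorded at delivery time. Deterministic for a
    fixed (recording, plan, config); ``seed`` is accepted for interface
    symmetry and recorded in the log attrs (the engine itself draws no random
    numbers).
    """
    cfg = config or ProtocolConfig()
    dcfg = detector_config or DetectorConfig(rate=recording.rate)
    if dcfg.rate != recording.rate:
        raise ValueError("detector_config.rate must match the recording rate")
    ch = recording.channel_labels.index(channel)
    so_filt = CausalBandpass(dcfg.so_band, dcfg.rate, dcfg.so_filter_order)
    so_det = SODetector(dcfg)
    sp_det = SpindleDetector(dcfg)
    hyp = recording.hypnogram
    arm_t = arming_time(hyp, cfg)

    rows: list[dict] = []
    last_cue = -np.inf
    slot_i = 0
    per_item_count: dict[str, int] = {}
    sham_count = 0

    for chunk in stream(recording, chunk_size):
        x = chunk[ch]
        sp_det.process(x)               # advance spindle state over the chunk
        events = so_det.process(so_filt.process(x))
        for ev in events:
            if slot_i >= len(plan.slot_sequence):
                break
            now = ev.trigger_time
            lst = sp_det.last_spindle_time(now)
            slot = plan.slot_sequence[slot_i]
            decision = gate_cue(now=now, stage=hyp.stage_at(now),
                                so_trigger=True, last_spindle_time=lst,
                                last_cue_time=last_cue,
                                armed=now >= arm_t, config=cfg,
                                slot_is_sham=(slot == SHAM))
            if decision is Decision.WITHHOLD:
                continue
            if decision is Decision.SHAM_MARK:
                sham_count += 1
                item, cat, cond, idx = SHAM, "", "sham", sham_count
            else:
                per_item_count[slot] = per_item_count.get(slot, 0) + 1
                item, cat, cond, idx = (slot, plan.category_of(slot),
                                        plan.condition_of(slot),
                                        per_item_count[slot])
            rows.append({"time": now, "item_id": item, "category": cat,
                         "condition": cond, "stage_at_event": hyp.stage_at(now),
                         "filtered_value_at_event": ev.peak_value,
                         "last_spindle_gap": now - lst,
                         "cue_index_within_item": idx})
            last_cue = now
            slot_i += 1

    log = pd.DataFrame(rows, columns=EVENT_LOG_COLUMNS)
    log.attrs["seed"] = seed
    log.attrs["arming_time"] = arm_t
    log.attrs["n_slots_planned"] = len(plan.slot_sequence)
    return log


def realized_cue_counts(log: pd.DataFrame) -> dict[str, int]:
    """Delivered sound-cue count per item (shams excluded)."""
    sounds = log[log["item_id"] != SHAM]
    return sounds.groupby("item_id").size().to_dict()


def label_sequence_positions(log: pd.DataFrame, plan: CuePlan) -> dict[str, int]:
    """Sequence-position labels: uncued-category items -> 0; the last four
    fully cued blocked items -> 1..4 counting from the end of the nap
    (4 = last). Partially cued blocked items carry no label."""
    counts = realized_cue_counts(log)
    labels = {it.item_id: 0 for it in plan.items if it.condition == "uncued"}
    blocked_full = [
        it.item_id for it in plan.items
        if it.condition == "blocked"
        and counts.get(it.item_id, 0) == plan.planned_reps_per_item
    ]
    sounds = log[log["item_id"] != SHAM]
    last_time = sounds.groupby("item_id")["time"].max()
    blocked_full.sort(key=lambda i: last_time[i])
    for rank, item in enumerate(reversed(blocked_full[-4:])):
        labels[item] = 4 - rank
    return labels


def write_event_log(log: pd.DataFrame, path: str | Path) -> None:
    log.to_csv(path, sep="\t", index=False)


def read_event_log(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
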