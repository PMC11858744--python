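"""Stimulus tables, task designs, trial records, aggregation and screening.

This module owns everything that happens before model fitting: validated
stimulus and design containers, the long-format trial CSV schema, per-group
aggregation into response tables (the fitting input), degenerate-responder
screening, and per-subject percentage tables for the rank-test checks.

Design conventions
------------------
* Each constant-stimuli group lists six tests around a reference; the seventh
  pair of a group is the reference compared against itself (an equal-viscosity
  catch pair), enabled by ``include_equal_pair``.
* When reference and tests share an appearance, adjacent groups share a
  physical pair (the top test of one group is the reference of the next).
  Under ``dedup_policy="within_appearance"`` such a pair is presented once and
  re-used, with the response flipped, when aggregating the second group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import presets

logger = logging.getLogger(__name__)

_SIDES = ("left", "right", "first", "second")
_OPPOSITE = {"left": "right", "right": "left", "first": "second", "second": "first"}

TRIAL_COLUMNS = [
    "participant_id",
    "task_id",
    "group_label",
    "reference_viscosity_cp",
    "test_viscosity_cp",
    "reference_appearance",
    "test_appearance",
    "reference_side",
    "response_test_thicker",
]


class ValidationError(ValueError):
    """Raised when an input violates a schema or design invariant."""


def _check_appearance(value: str) -> str:
    if value not in presets.APPEARANCES:
        raise ValidationError(f"unknown appearance {value!r}")
    return value


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusSample:
    """One physical fluid sample: id, appearance and measured viscosity."""

    sample_id: int
    appearance: str
    viscosity: float  # cP

    def __post_init__(self) -> None:
        _check_appearance(self.appearance)
        if not self.viscosity > 0:
            raise ValidationError(
                f"sample {self.sample_id}: viscosity must be positive, "
                f"got {self.viscosity}"
            )


@dataclass(frozen=True)
class GroupDesign:
    """One constant-stimuli group: a reference bracketed by ordered tests.

    ``equal_test`` is the test-side counterpart of the reference sample used
    for the 7th (catch) pair: in same-appearance tasks it is the reference
    itself, in mixed-appearance tasks the same sample id from the test-side
    table (whose measured viscosity differs slightly).
    """

    label: str
    reference: StimulusSample
    tests: tuple[StimulusSample, ...]
    include_equal_pair: bool = True
    equal_test: StimulusSample | None = None

    def __post_init__(self) -> None:
        viscs = [t.viscosity for t in self.tests]
        if sorted(viscs) != viscs:
            raise ValidationError(f"group {self.label}: tests not sorted ascending")
        if len(set(viscs)) != len(viscs):
            raise ValidationError(f"group {self.label}: duplicate test viscosities")
        below = any(v < self.reference.viscosity for v in viscs)
        above = any(v > self.reference.viscosity for v in viscs)
        if not (below and above):
            raise ValidationError(
                f"group {self.label}: tests must bracket the reference "
                f"({self.reference.viscosity} cP)"
            )


@dataclass(frozen=True)
class PairSpec:
    """A physical reference/test pairing and the groups that use it."""

    reference: StimulusSample
    test: StimulusSample
    group_labels: tuple[str, ...]

    @property
    def home_group(self) -> str:
        return self.group_labels[0]


@dataclass(frozen=True)
class ExperimentDesign:
    """De-duplicated pair list for one task."""

    task_id: str
    pairs: tuple[PairSpec, ...]
    dedup_policy: str  # "within_appearance" | "none"

    def __post_init__(self) -> None:
        if self.dedup_policy not in ("within_appearance", "none"):
            raise ValidationError(f"unknown dedup_policy {self.dedup_policy!r}")
        if self.dedup_policy == "within_appearance":
            keys = [_pair_key(p.reference, p.test) for p in self.pairs]
            if len(set(keys)) != len(keys):
                raise ValidationError("duplicate physical pair in de-duplicated design")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class TrialRecord:
    """One participant's single binary judgement of one stimulus pair."""

    participant_id: str
    task_id: str
    group_label: str
    reference_viscosity: float
    test_viscosity: float
    reference_appearance: str
    test_appearance: str
    reference_side: str
    response_test_thicker: bool

    def __post_init__(self) -> None:
        _check_appearance(self.reference_appearance)
        _check_appearance(self.test_appearance)
        if self.reference_side not in _SIDES:
            raise ValidationError(f"unknown side {self.reference_side!r}")
        if self.reference_viscosity <= 0 or self.test_viscosity <= 0:
            raise ValidationError("viscosities must be positive")

    def key(self) -> tuple:
        """Uniqueness key: each pair is judged once per participant."""
        return (
            self.participant_id,
            self.task_id,
            self.reference_viscosity,
            self.test_viscosity,
            self.reference_appearance,
            self.test_appearance,
        )


@dataclass(frozen=True)
class ResponseRow:
    """Aggregated responses for one test viscosity of one group.

    ``k_thicker`` of ``n_total`` participants judged the test thicker.  When
    built from trial records the per-response participant identities and the
    aligned 0/1 responses are retained (the bootstrap resamples at this
    level); count-only rows are allowed for synthetic frequency tables.
    """

    test_viscosity: float
    test_appearance: str
    k_thicker: int
    n_total: int
    participant_ids: tuple[str, ...] = ()
    responses: tuple[int, ...] = ()  # 1 = "test thicker", aligned with ids

    def __post_init__(self) -> None:
        if not 0 <= self.k_thicker <= self.n_total:
            raise ValidationError(
                f"row at {self.test_viscosity} cP: need 0 <= k <= n, "
                f"got k={self.k_thicker}, n={self.n_total}"
            )
        if self.n_total <= 0:
            raise ValidationError(f"row at {self.test_viscosity} cP has no responses")
        if self.responses:
            if len(self.responses) != self.n_total or sum(self.responses) != self.k_thicker:
                raise ValidationError(
                    f"row at {self.test_viscosity} cP: responses disagree with k/n"
                )


@dataclass(frozen=True)
class ResponseTable:
    """Per-group fitting input: k/n 'thicker' counts per test viscosity."""

    group_label: str
    reference_viscosity: float
    rows: tuple[ResponseRow, ...]

    def __post_init__(self) -> None:
        viscs = [r.test_viscosity for r in self.rows]
        if sorted(viscs) != viscs:
            raise ValidationError("response rows must be sorted by test viscosity")

    @classmethod
    def from_counts(
        cls,
        group_label: str,
        reference_viscosity: float,
        counts: Sequence[tuple[float, int, int]],
        test_appearance: str = "transparent",
    ) -> "ResponseTable":
        """Build a count-only table from (test_viscosity, k, n) triples."""
        rows = tuple(
            ResponseRow(eta, test_appearance, int(k), int(n))
            for eta, k, n in sorted(counts)
        )
        return cls(group_label, reference_viscosity, rows)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (eta, k, n) as float arrays for likelihood code."""
        eta = np.array([r.test_viscosity for r in self.rows], dtype=float)
        k = np.array([r.k_thicker for r in self.rows], dtype=float)
        n = np.array([r.n_total for r in self.rows], dtype=float)
        return eta, k, n


# ---------------------------------------------------------------------------
# stimulus and design construction
# ---------------------------------------------------------------------------


def builtin_stimuli(appearance: str) -> list[StimulusSample]:
    """The bundled 21-sample inventory for one appearance."""
    _check_appearance(appearance)
    col = 0 if appearance == "transparent" else 1
    return [
        StimulusSample(sid, appearance, viscs[col])
        for sid, viscs in presets.VISCOSITY_TABLE.items()
    ]


def load_stimulus_table(path: str | Path) -> list[StimulusSample]:
    """Read a stimulus CSV with columns sample_id, appearance, viscosity_cp."""
    df = pd.read_csv(path)
    required = {"sample_id", "appearance", "viscosity_cp"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    samples: list[StimulusSample] = []
    seen: set[tuple[int, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            sample = StimulusSample(
                int(row.sample_id), str(row.appearance), float(row.viscosity_cp)
            )
        except (TypeError, ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: line {i}: {exc}") from exc
        key = (sample.sample_id, sample.appearance)
        if key in seen:
            raise ValidationError(f"{path}: line {i}: duplicate sample key {key}")
        seen.add(key)
        samples.append(sample)
    return samples


def write_stimulus_table(samples: Iterable[StimulusSample], path: str | Path) -> None:
    df = pd.DataFrame(
        [(s.sample_id, s.appearance, s.viscosity) for s in samples],
        columns=["sample_id", "appearance", "viscosity_cp"],
    )
    df.to_csv(path, index=False)


def build_group_designs(
    stimuli: Sequence[StimulusSample],
    grouping_spec: Mapping[str, tuple[int, Sequence[int]]] | None = None,
    *,
    test_stimuli: Sequence[StimulusSample] | None = None,
    include_equal_pair: bool = True,
) -> list[GroupDesign]:
    """Build the A-E groups from a stimulus table and a grouping spec.

    ``stimuli`` supplies the references.  For mixed-appearance tasks pass the
    test-side table via ``test_stimuli``; it defaults to ``stimuli``.
    ``grouping_spec`` maps label -> (reference sample id, test sample ids) and
    defaults to the bundled layout.
    """
    if grouping_spec is None:
        grouping_spec = presets.GROUPINGS
    if test_stimuli is None:
        test_stimuli = stimuli
    ref_by_id = {s.sample_id: s for s in stimuli}
    test_by_id = {s.sample_id: s for s in test_stimuli}
    groups = []
    for label, (ref_id, test_ids) in grouping_spec.items():
        if ref_id not in ref_by_id:
            raise ValidationError(f"group {label}: unknown reference sample {ref_id}")
        unknown = [t for t in test_ids if t not in test_by_id]
        if unknown:
            raise ValidationError(f"group {label}: unknown test samples {unknown}")
        tests = tuple(sorted((test_by_id[t] for t in test_ids), key=lambda s: s.viscosity))
        groups.append(
            GroupDesign(
                label, ref_by_id[ref_id], tests, include_equal_pair,
                equal_test=test_by_id.get(ref_id),
            )
        )
    return groups


def _pair_key(a: StimulusSample, b: StimulusSample) -> tuple:
    return tuple(sorted([(a.appearance, a.viscosity), (b.appearance, b.viscosity)]))


def enumerate_unique_pairs(
    groups: Sequence[GroupDesign],
    include_equal_pair: bool = True,
    dedup_policy: str = "within_appearance",
    task_id: str = "",
) -> ExperimentDesign:
    """List every pair a participant sees, counting shared pairs once.

    With six tests plus the equal-viscosity catch pair per group, the bundled
    same-appearance layout yields 7 pairs in the outer groups and 6 in the
    inner ones (their boundary pair is re-used), 32 in total; mixed-appearance
    layouts have no physical duplicates and keep all 35.
    """
    pair_specs: list[PairSpec] = []
    by_key: dict[tuple, int] = {}
    for group in groups:
        candidates = list(group.tests)
        if include_equal_pair:
            candidates.append(group.equal_test or group.reference)
        for test in candidates:
            key = _pair_key(group.reference, test)
            if dedup_policy == "within_appearance" and key in by_key:
                idx = by_key[key]
                prev = pair_specs[idx]
                pair_specs[idx] = PairSpec(
                    prev.reference, prev.test, prev.group_labels + (group.label,)
                )
                continue
            by_key[key] = len(pair_specs)
            pair_specs.append(PairSpec(group.reference, test, (group.label,)))
    return ExperimentDesign(task_id, tuple(pair_specs), dedup_policy)


# ---------------------------------------------------------------------------
# trial I/O
# ---------------------------------------------------------------------------


def write_trials(records: Iterable[TrialRecord], path: str | Path) -> None:
    """Write trials to the long-format CSV schema (one row per judgement)."""
    df = pd.DataFrame(
        [
            (
                r.participant_id,
                r.task_id,
                r.group_label,
                r.reference_viscosity,
                r.test_viscosity,
                r.reference_appearance,
                r.test_appearance,
                r.reference_side,
                int(r.response_test_thicker),
            )
            for r in records
        ],
        columns=TRIAL_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_trials(path: str | Path) -> list[TrialRecord]:
    """Read and validate a trial CSV; rejects duplicate judgements."""
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    records: list[TrialRecord] = []
    seen: set[tuple] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rec = TrialRecord(
                participant_id=str(row.participant_id),
                task_id=str(row.task_id),
                group_label=str(row.group_label),
                reference_viscosity=float(row.reference_viscosity_cp),
                test_viscosity=float(row.test_viscosity_cp),
                reference_appearance=str(row.reference_appearance),
                test_appearance=str(row.test_appearance),
                reference_side=str(row.reference_side),
                response_test_thicker=bool(int(row.response_test_thicker)),
            )
        except (TypeError, ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: line {i}: {exc}") from exc
        key = rec.key()
        if key in seen:
            raise ValidationError(f"{path}: line {i}: duplicate trial {key}")
        seen.add(key)
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# screening and aggregation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreeningReport:
    """Degenerate-response flags per (participant, task); nothing is removed."""

    flags: Mapping[tuple[str, str], tuple[str, ...]]
    n_participants: int

    def flagged(self) -> list[tuple[str, str, tuple[str, ...]]]:
        return [(p, t, f) for (p, t), f in sorted(self.flags.items()) if f]


def screen_participants(trials: Sequence[TrialRecord]) -> ScreeningReport:
    """Flag participants who always chose one response or one side."""
    if not trials:
        raise ValidationError("no trials to screen")
    by_pt: dict[tuple[str, str], list[TrialRecord]] = {}
    for t in trials:
        by_pt.setdefault((t.participant_id, t.task_id), []).append(t)
    flags: dict[tuple[str, str], tuple[str, ...]] = {}
    for key, recs in by_pt.items():
        found: list[str] = []
        responses = [r.response_test_thicker for r in recs]
        if all(responses):
            found.append("always_test")
        if not any(responses):
            found.append("always_reference")
        chosen = [
            _OPPOSITE[r.reference_side] if r.response_test_thicker else r.reference_side
            for r in recs
        ]
        if len(set(chosen)) == 1 and len(chosen) > 1:
            found.append(f"always_{chosen[0]}")
        flags[key] = tuple(found)
    return ScreeningReport(flags, n_participants=len({t.participant_id for t in trials}))


def aggregate(trials: Sequence[TrialRecord], group: GroupDesign) -> ResponseTable:
    """Pool responses over participants into a per-group response table.

    Trials whose stored orientation is flipped relative to this group (the
    shared boundary pair stored under the adjacent group) are re-used with the
    response inverted: "test thicker" for (ref=r, test=t) is "reference
    thicker" for (ref=t, test=r).
    """
    if not trials:
        raise ValidationError("no trials to aggregate")
    targets: list[StimulusSample] = list(group.tests)
    if group.include_equal_pair:
        targets.append(group.equal_test or group.reference)
    ref = group.reference
    index: dict[tuple, list[TrialRecord]] = {}
    for t in trials:
        key = (
            _vkey(t.reference_viscosity),
            t.reference_appearance,
            _vkey(t.test_viscosity),
            t.test_appearance,
        )
        index.setdefault(key, []).append(t)
    rows: list[ResponseRow] = []
    for test in sorted(targets, key=lambda s: s.viscosity):
        pids: list[str] = []
        resp: list[int] = []
        direct_key = (
            _vkey(ref.viscosity), ref.appearance, _vkey(test.viscosity), test.appearance,
        )
        for t in index.get(direct_key, ()):
            pids.append(t.participant_id)
            resp.append(int(t.response_test_thicker))
        equal_pair = _vkey(test.viscosity) == _vkey(ref.viscosity) and (
            test.appearance == ref.appearance
        )
        if not equal_pair:
            flipped_key = (
                _vkey(test.viscosity), test.appearance, _vkey(ref.viscosity), ref.appearance,
            )
            for t in index.get(flipped_key, ()):
                pids.append(t.participant_id)
                resp.append(int(not t.response_test_thicker))
        if resp:
            rows.append(
                ResponseRow(
                    test.viscosity,
                    test.appearance,
                    int(sum(resp)),
                    len(resp),
                    tuple(pids),
                    tuple(resp),
                )
            )
    if not rows:
        raise ValidationError(f"group {group.label}: no matching trials")
    return ResponseTable(group.label, ref.viscosity, tuple(rows))


def _vkey(v: float) -> float:
    """Viscosity matching key, tolerant to CSV round-tripping."""
    return round(v, 6)


def per_subject_percentages(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Percent 'test thicker' per participant and group (long format).

    Groups are attributed by the stored label, i.e. a shared boundary pair
    counts toward the group it was presented under.
    """
    if not trials:
        raise ValidationError("no trials given")
    df = pd.DataFrame(
        [
            (t.participant_id, t.group_label, int(t.response_test_thicker))
            for t in trials
        ],
        columns=["participant_id", "group_label", "response"],
    )
    out = (
        df.groupby(["participant_id", "group_label"])["response"]
        .agg(n_trials="count", percent_test_thicker=lambda s: 100.0 * s.mean())
        .reset_index()
    )
    return out
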