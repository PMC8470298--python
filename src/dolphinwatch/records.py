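"""Data model for scan-sampling focal follows of dolphin groups.

A *focal follow* is an ordered sequence of instantaneous scans of one dolphin
group, taken at a fixed 3-minute interval.  Each scan records the predominant
behavioural state of the group, the number of dolphin-watching vessels within
300 m, and (when vessels are present) compliance of those vessels with the
local code of conduct, plus group-level covariates.  Consecutive scan pairs
are the atomic unit of the Markov analysis: each pair yields one behavioural
transition labelled *control* (no vessels at either scan), *impact* (vessels
at both scans) or *transition* (vessel presence changed between the scans).
Transition-condition pairs are never counted in either chain.

The ethogram defines six mutually exclusive states (resting, travelling,
socialising, diving, milling, feeding); feeding is accepted on input but
flagged, since analyses run on the five states observed in the field.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: The five behavioural states the analyses operate on, in fixed matrix order.
OBSERVED_STATES: tuple[str, ...] = ("REST", "TRAV", "SOC", "DIV", "MIL")

#: Feeding is part of the ethogram but excluded from the 5-state analysis.
FEEDING_STATE = "FEED"

#: Full ethogram vocabulary.
ETHOGRAM: tuple[str, ...] = OBSERVED_STATES + (FEEDING_STATE,)

#: Case-insensitive aliases accepted on input (field sheets abbreviate
#: inconsistently; both British and American spellings occur).
STATE_ALIASES: dict[str, str] = {
    "REST": "REST", "RESTING": "REST", "RES": "REST",
    "TRAV": "TRAV", "TRAVELLING": "TRAV", "TRAVELING": "TRAV", "TRA": "TRAV",
    "SOC": "SOC", "SOCIALISING": "SOC", "SOCIALIZING": "SOC",
    "DIV": "DIV", "DIVING": "DIV",
    "MIL": "MIL", "MILLING": "MIL",
    "FEED": "FEED", "FEEDING": "FEED",
}

COHESION_LEVELS: tuple[str, ...] = ("low", "intermediate", "high")
RESPONSE_LEVELS: tuple[str, ...] = ("avoidance", "neutral", "attraction")

#: Follow-length bounds implied by the local observation guidelines
#: (6 min = 2 scans up to 45 min = 15 scans). Violations warn, never error.
MIN_SCANS, MAX_SCANS = 2, 15

#: Duration of one scan interval / transition unit, in minutes.
SCAN_INTERVAL_MIN = 3.0

REQUIRED_COLUMNS = ("follow_id", "scan_index", "state", "n_vessels")
OPTIONAL_COLUMNS = ("compliant", "group_size", "cohesion", "response", "date")


class Condition(str, enum.Enum):
    """Vessel-presence condition of a consecutive-scan pair."""

    CONTROL = "control"
    IMPACT = "impact"
    TRANSITION = "transition"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ScanTableError(ValueError):
    """Raised when a scan table violates the schema; carries row context."""


def normalise_state(label: str, aliases: Mapping[str, str] | None = None) -> str:
    """Map a raw state label to its canonical ethogram code.

    Raises ``ScanTableError`` naming the label when it is not in the
    (case-insensitive) vocabulary.
    """
    table = STATE_ALIASES if aliases is None else {**STATE_ALIASES, **aliases}
    key = str(label).strip().upper()
    if key not in table:
        raise ScanTableError(f"unknown behavioural state label {label!r}")
    return table[key]


@dataclass(frozen=True)
class Scan:
    """One instantaneous scan of the focal group.

    ``compliant`` is only meaningful when vessels are present; with
    ``n_vessels == 0`` there is nothing to comply, so the field must be None.
    """

    follow_id: str
    scan_index: int
    state: str
    n_vessels: int
    compliant: bool | None = None
    group_size: int | None = None
    cohesion: str | None = None
    response: str | None = None

    def __post_init__(self) -> None:
        if self.state not in ETHOGRAM:
            raise ScanTableError(f"unknown behavioural state label {self.state!r}")
        if self.n_vessels < 0:
            raise ScanTableError(f"n_vessels must be >= 0, got {self.n_vessels}")
        if self.n_vessels == 0 and self.compliant is not None:
            raise ScanTableError(
                "compliant is undefined when no vessels are present "
                f"(follow {self.follow_id}, scan {self.scan_index})"
            )
        if self.cohesion is not None and self.cohesion not in COHESION_LEVELS:
            raise ScanTableError(f"unknown cohesion level {self.cohesion!r}")
        if self.response is not None and self.response not in RESPONSE_LEVELS:
            raise ScanTableError(f"unknown response level {self.response!r}")
        if self.group_size is not None and self.group_size < 1:
            raise ScanTableError(f"group_size must be positive, got {self.group_size}")

    @property
    def time_minutes(self) -> float:
        """Elapsed time of this scan within the follow (index x 3 min)."""
        return self.scan_index * SCAN_INTERVAL_MIN

    @property
    def vessels_present(self) -> bool:
        return self.n_vessels >= 1


@dataclass(frozen=True)
class FocalFollow:
    """An ordered sequence of 3-min scans of one dolphin group on one day."""

    follow_id: str
    scans: tuple[Scan, ...]
    date: str | None = None

    def __post_init__(self) -> None:
        indices = [s.scan_index for s in self.scans]
        for a, b in zip(indices, indices[1:]):
            if b != a + 1:
                raise ScanTableError(
                    f"follow {self.follow_id}: scan_index not consecutive "
                    f"({a} followed by {b})"
                )
        n = len(self.scans)
        if n < MIN_SCANS or n > MAX_SCANS:
            warnings.warn(
                f"follow {self.follow_id} has {n} scans, outside the usual "
                f"{MIN_SCANS}-{MAX_SCANS} scan protocol",
                stacklevel=2,
            )
        for s in self.scans:
            if s.follow_id != self.follow_id:
                raise ScanTableError(
                    f"scan follow_id {s.follow_id!r} does not match follow "
                    f"{self.follow_id!r}"
                )

    def __len__(self) -> int:
        return len(self.scans)

    @property
    def duration_minutes(self) -> float:
        """Span from first to last scan; a 2-scan follow spans 3 min."""
        if len(self.scans) < 2:
            return 0.0
        return (self.scans[-1].scan_index - self.scans[0].scan_index) * SCAN_INTERVAL_MIN


@dataclass(frozen=True)
class TransitionSample:
    """A (preceding state, succeeding state, condition) triple from one pair
    of consecutive scans within a follow."""

    preceding: str
    succeeding: str
    condition: Condition
    follow_id: str


@dataclass
class TransitionPool:
    """Labelled transition samples pooled over follows, with bookkeeping."""

    samples: list[TransitionSample]

    @property
    def counts(self) -> dict[Condition, int]:
        out = {c: 0 for c in Condition}
        for s in self.samples:
            out[s.condition] += 1
        return out

    @property
    def control_fraction(self) -> float:
        """Share of control among the analysable (control + impact) samples.

        Transition-condition pairs are excluded from the denominator, as they
        enter neither chain.
        """
        c = self.counts
        denom = c[Condition.CONTROL] + c[Condition.IMPACT]
        if denom == 0:
            return float("nan")
        return c[Condition.CONTROL] / denom

    def of_condition(self, condition: Condition) -> list[TransitionSample]:
        return [s for s in self.samples if s.condition == condition]

    def __len__(self) -> int:
        return len(self.samples)


def classify_pair(n_vessels_first: int, n_vessels_second: int) -> Condition:
    """Label one consecutive-scan pair by vessel presence at its endpoints.

    Exhaustive and exclusive: no vessels at either scan -> control; at least
    one vessel at both scans -> impact; presence differing between the two
    scans -> transition (excluded from both chains downstream).
    """
    first, second = n_vessels_first >= 1, n_vessels_second >= 1
    if not first and not second:
        return Condition.CONTROL
    if first and second:
        return Condition.IMPACT
    return Condition.TRANSITION


def label_conditions(follow: FocalFollow) -> list[TransitionSample]:
    """Extract one labelled TransitionSample per consecutive scan pair.

    A follow with fewer than 2 scans yields no pairs; that is logged, not an
    error (n scans always yield n - 1 samples).
    """
    if len(follow) < 2:
        logger.info("follow %s has < 2 scans; no transitions", follow.follow_id)
        return []
    out = []
    for a, b in zip(follow.scans, follow.scans[1:]):
        out.append(
            TransitionSample(
                preceding=a.state,
                succeeding=b.state,
                condition=classify_pair(a.n_vessels, b.n_vessels),
                follow_id=follow.follow_id,
            )
        )
    return out


def pool_transitions(follows: Iterable[FocalFollow]) -> TransitionPool:
    """Concatenate labelled samples across follows.

    The pool records counts per condition and the control fraction
    (control / (control + impact)).
    """
    samples: list[TransitionSample] = []
    for f in follows:
        samples.extend(label_conditions(f))
    pool = TransitionPool(samples)
    c = pool.counts
    logger.info(
        "pooled %d transitions: %d control, %d impact, %d transition-condition",
        len(pool), c[Condition.CONTROL], c[Condition.IMPACT], c[Condition.TRANSITION],
    )
    return pool


def _parse_bool(value: object) -> bool | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip().lower()
    if s in ("", "na", "nan", "none"):
        return None
    if s in ("1", "true", "t", "yes", "y"):
        return True
    if s in ("0", "false", "f", "no", "n"):
        return False
    raise ScanTableError(f"cannot parse boolean value {value!r}")


def _parse_optional_int(value: object) -> int | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if s in ("", "na", "nan", "none"):
        return None
    return int(float(s))


def _parse_optional_cat(value: object, levels: Sequence[str], name: str) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip().lower()
    if s in ("", "na", "nan", "none"):
        return None
    if s not in levels:
        raise ScanTableError(f"unknown {name} level {value!r}")
    return s


def read_scan_table(
    path,
    column_map: Mapping[str, str] | None = None,
    state_aliases: Mapping[str, str] | None = None,
) -> list[FocalFollow]:
    """Read a focal-follow scan table from CSV.

    Parameters
    ----------
    path
        CSV file with a header row; comma separated, UTF-8. Required columns:
        ``follow_id, scan_index, state, n_vessels``; optional: ``compliant,
        group_size, cohesion, response, date``. Missing optional fields are
        empty strings.
    column_map
        Optional mapping from the canonical column names to the names used in
        the file.
    state_aliases
        Extra state-label aliases, merged over the built-in vocabulary.

    Returns
    -------
    list of FocalFollow, grouped by follow_id with scans ordered by
    scan_index. Follows are returned in first-appearance order.

    Raises
    ------
    ScanTableError
        On a missing required column, an unknown state label (named in the
        message), or a non-consecutive scan_index within a follow. Malformed
        rows are reported with their file line numbers.
    """
    colmap = dict(column_map or {})
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = {colmap.get(c, c): c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS}
    df = df.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ScanTableError(f"missing required column(s): {', '.join(missing)}")

    scans_by_follow: dict[str, list[Scan]] = {}
    dates: dict[str, str | None] = {}
    errors: list[str] = []
    feed_rows = 0
    for pos, row in enumerate(df.itertuples(index=False)):
        line_no = pos + 2  # header is line 1
        rec = row._asdict()
        try:
            state = normalise_state(rec["state"], state_aliases)
            if state == FEEDING_STATE:
                feed_rows += 1
            n_vessels = int(float(rec["n_vessels"]))
            compliant = _parse_bool(rec.get("compliant"))
            if n_vessels == 0:
                compliant = None  # nothing present to comply
            scan = Scan(
                follow_id=str(rec["follow_id"]).strip(),
                scan_index=int(float(rec["scan_index"])),
                state=state,
                n_vessels=n_vessels,
                compliant=compliant,
                group_size=_parse_optional_int(rec.get("group_size")),
                cohesion=_parse_optional_cat(rec.get("cohesion"), COHESION_LEVELS, "cohesion"),
                response=_parse_optional_cat(rec.get("response"), RESPONSE_LEVELS, "response"),
            )
        except (ScanTableError, ValueError) as exc:
            errors.append(f"line {line_no}: {exc}")
            continue
        scans_by_follow.setdefault(scan.follow_id, []).append(scan)
        if "date" in rec:
            d = str(rec["date"]).strip()
            dates.setdefault(scan.follow_id, d or None)
    if errors:
        raise ScanTableError("malformed scan table:\n" + "\n".join(errors))
    if feed_rows:
        warnings.warn(
            f"{feed_rows} scan(s) recorded as {FEEDING_STATE}; feeding is part "
            "of the ethogram but excluded from the 5-state analysis by default",
            stacklevel=2,
        )

    follows = []
    for fid, scans in scans_by_follow.items():
        scans = sorted(scans, key=lambda s: s.scan_index)
        follows.append(FocalFollow(follow_id=fid, scans=tuple(scans), date=dates.get(fid)))
    return follows


def follows_to_frame(follows: Iterable[FocalFollow]) -> pd.DataFrame:
    """Serialise follows back to the scan-table schema (round-trip safe)."""
    rows = []
    for f in follows:
        for s in f.scans:
            rows.append(
                {
                    "follow_id": s.follow_id,
                    "scan_index": s.scan_index,
                    "state": s.state,
                    "n_vessels": s.n_vessels,
                    "compliant": "" if s.compliant is None else str(int(s.compliant)),
                    "group_size": "" if s.group_size is None else s.group_size,
                    "cohesion": s.cohesion or "",
                    "response": s.response or "",
                    "date": f.date or "",
                }
            )
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS))


def write_scan_table(follows: Iterable[FocalFollow], path) -> None:
    follows_to_frame(follows).to_csv(path, index=False)


def transitions_to_frame(samples: Iterable[TransitionSample]) -> pd.DataFrame:
    rows = [
        {
            "follow_id": s.follow_id,
            "preceding": s.preceding,
            "succeeding": s.succeeding,
            "condition": s.condition.value,
        }
        for s in samples
    ]
    return pd.DataFrame(rows, columns=["follow_id", "preceding", "succeeding", "condition"])


def write_transitions(samples: Iterable[TransitionSample], path) -> None:
    transitions_to_frame(samples).to_csv(path, index=False)


def read_transitions(path) -> list[TransitionSample]:
    df = pd.read_csv(path, dtype=str)
    return [
        TransitionSample(
            preceding=normalise_state(r.preceding),
            succeeding=normalise_state(r.succeeding),
            condition=Condition(r.condition),
            follow_id=str(r.follow_id),
        )
        for r in df.itertuples(index=False)
    ]
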