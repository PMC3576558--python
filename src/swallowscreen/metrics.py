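"""PAS binarization, worst-case rollup, and screening-accuracy metrics.

The 8-point Penetration-Aspiration Scale is collapsed to binary: scores
<= 2 (normal airway protection or transient high penetration) are "safe",
scores >= 3 (deeper airway entry without clearance) are "unsafe".  Labels
roll up worst-case from subswallows to a bolus and from boluses to a
participant: one unsafe member makes the aggregate unsafe.

Throughout, **unsafe is the positive class** of every 2x2 contingency
table.  Metrics with a zero denominator are reported as undefined (None),
never as 0 or 100, since small per-participant tables can have empty cells.
Percentages are rounded half-away-from-zero for display; raw values are
kept in serialized output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

from .classifier import SAFE, UNSAFE

RESOLUTIONS = ("swallow", "bolus", "participant")


def collapse_pas(score: int) -> str:
    """Binary collapse of a PAS score: <=2 -> safe, >=3 -> unsafe."""
    if not 1 <= int(score) <= 8:
        raise ValueError(f"PAS score must be in 1..8, got {score}")
    return SAFE if score <= 2 else UNSAFE


def rollup(labels: Sequence[str]) -> str:
    """Worst-case aggregation: unsafe iff any member is unsafe."""
    labels = list(labels)
    if not labels:
        raise ValueError("cannot roll up an empty label list")
    for lab in labels:
        if lab not in (SAFE, UNSAFE):
            raise ValueError(f"unknown label {lab!r}")
    return UNSAFE if UNSAFE in labels else SAFE


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts with unsafe as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def build_contingency(
    truth: dict[tuple, str] | Sequence[str],
    device: dict[tuple, str] | Sequence[str],
) -> ContingencyTable:
    """Tally device calls against gold-standard labels.

    Accepts either two key->label mappings (matched by key) or two equal
    length sequences (matched by position).
    """
    if isinstance(truth, dict) != isinstance(device, dict):
        raise ValueError("truth and device must both be dicts or both sequences")
    if isinstance(truth, dict):
        if set(truth) != set(device):
            raise ValueError("truth and device keys do not match")
        pairs = [(truth[k], device[k]) for k in sorted(truth)]
    else:
        if len(truth) != len(device):
            raise ValueError(
                f"length mismatch: {len(truth)} truth vs {len(device)} device labels"
            )
        pairs = list(zip(truth, device))
    tp = sum(1 for t, d in pairs if t == UNSAFE and d == UNSAFE)
    fp = sum(1 for t, d in pairs if t == SAFE and d == UNSAFE)
    tn = sum(1 for t, d in pairs if t == SAFE and d == SAFE)
    fn = sum(1 for t, d in pairs if t == UNSAFE and d == SAFE)
    return ContingencyTable(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass(frozen=True)
class ScreeningMetrics:
    """Screening accuracy at one resolution; None marks an undefined metric."""

    resolution: str
    sensitivity: float | None
    specificity: float | None
    npv: float | None
    ppv: float | None
    false_positive_rate: float | None
    false_negative_rate: float | None
    table: ContingencyTable

    def to_dict(self) -> dict:
        d = asdict(self)
        d["table"] = asdict(self.table)
        return d


def _pct(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def compute_metrics(t: ContingencyTable, resolution: str = "swallow") -> ScreeningMetrics:
    """Sensitivity/specificity/NPV/PPV and error rates from a 2x2 table."""
    if t.total < 1:
        raise ValueError("empty contingency table")
    if resolution not in RESOLUTIONS:
        raise ValueError(f"unknown resolution {resolution!r}")
    sens = _pct(t.tp, t.tp + t.fn)
    spec = _pct(t.tn, t.tn + t.fp)
    return ScreeningMetrics(
        resolution=resolution,
        sensitivity=sens,
        specificity=spec,
        npv=_pct(t.tn, t.tn + t.fn),
        ppv=_pct(t.tp, t.tp + t.fp),
        false_positive_rate=None if spec is None else 100.0 - spec,
        false_negative_rate=None if sens is None else 100.0 - sens,
        table=t,
    )


def prevalence(labels: Sequence[str]) -> tuple[float, int]:
    """Unsafe prevalence as (raw percentage, integer-rounded percentage)."""
    labels = list(labels)
    if not labels:
        raise ValueError("cannot compute prevalence of an empty label list")
    raw = 100.0 * sum(1 for lab in labels if lab == UNSAFE) / len(labels)
    return raw, round_half_away(raw)


def round_half_away(x: float) -> int:
    """Round half away from zero (the convention for displayed percentages)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


@dataclass(frozen=True)
class AgreementResult:
    """Cohen's kappa for two binary raters: (p_o - p_e) / (1 - p_e)."""

    p_observed: float
    p_expected: float
    kappa: float


def cohen_kappa(a: Sequence[str], b: Sequence[str]) -> AgreementResult:
    """Chance-corrected agreement between two binary label vectors."""
    a, b = list(a), list(b)
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("empty label vectors")
    n = len(a)
    p_o = sum(1 for x, y in zip(a, b) if x == y) / n
    p_e = 0.0
    for lab in (SAFE, UNSAFE):
        p_e += (sum(1 for x in a if x == lab) / n) * (sum(1 for y in b if y == lab) / n)
    if p_e >= 1.0:
        raise ValueError("kappa undefined: chance agreement p_e = 1 (degenerate marginals)")
    kappa = (p_o - p_e) / (1.0 - p_e)
    return AgreementResult(p_observed=p_o, p_expected=p_e, kappa=kappa)


# ---------------------------------------------------------------------------
# rollup across resolutions + report rendering
# ---------------------------------------------------------------------------

def rollup_table(labels: dict[tuple, str], levels: int) -> dict[tuple, str]:
    """Roll a key->label mapping up by truncating keys to ``levels`` fields."""
    grouped: dict[tuple, list[str]] = {}
    for key, lab in labels.items():
        grouped.setdefault(tuple(key[:levels]), []).append(lab)
    return {k: rollup(v) for k, v in grouped.items()}


def metrics_at_all_resolutions(
    truth: dict[tuple, str], device: dict[tuple, str]
) -> dict[str, ScreeningMetrics]:
    """Swallow-, bolus-, and participant-level metrics from subswallow labels.

    Keys are (participant, task, bolus, subswallow); bolus level truncates
    to (participant, task, bolus), participant level to (participant,).
    """
    out: dict[str, ScreeningMetrics] = {}
    for resolution, levels in (("swallow", 4), ("bolus", 3), ("participant", 1)):
        t = rollup_table(truth, levels)
        d = rollup_table(device, levels)
        out[resolution] = compute_metrics(build_contingency(t, d), resolution)
    return out


def _fmt(v: float | None) -> str:
    return "undef" if v is None else str(round_half_away(v))


def render_report(metrics: dict[str, ScreeningMetrics]) -> str:
    """Text table of accuracy statistics with per-resolution columns."""
    cols = [r for r in RESOLUTIONS if r in metrics]
    header = {"swallow": "Per swallow", "bolus": "Per bolus", "participant": "Per participant"}
    rows = [
        ("Sensitivity (%)", "sensitivity"),
        ("Specificity (%)", "specificity"),
        ("Negative predictive value (%)", "npv"),
        ("Positive predictive value (%)", "ppv"),
        ("False-positive rate (%)", "false_positive_rate"),
        ("False-negative rate (%)", "false_negative_rate"),
    ]
    width = max(len(r[0]) for r in rows)
    lines = ["Parameter".ljust(width) + "".join(header[c].rjust(18) for c in cols)]
    for label, attr in rows:
        line = label.ljust(width)
        for c in cols:
            line += _fmt(getattr(metrics[c], attr)).rjust(18)
        lines.append(line)
    for c in cols:
        t = metrics[c].table
        lines.append(
            f"[{c}] n={t.total} unsafe={t.tp + t.fn} "
            f"(TP={t.tp} FP={t.fp} TN={t.tn} FN={t.fn})"
        )
    return "\n".join(lines)
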