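"""Per-step cost and time accounting for the laboratory workflow.

Currency is held as integer euro-cents so that column sums are exact;
durations are held as integer seconds.  Cells printed as absent ("—", "")
or as a below-resolution bound ("<0.01") contribute zero to every sum.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "CostStep",
    "CostLedger",
    "CostTotals",
    "parse_duration",
    "format_duration",
    "parse_currency",
    "aggregate",
    "load_steps_tsv",
    "reference_workflow_ledger",
]

_DURATION_RE = re.compile(r"^(\d+):([0-5]?\d)(?::([0-5]?\d))?$")


def parse_duration(text: str, field_name: str = "duration") -> int:
    """Parse ``H:MM:SS`` or ``H:MM`` into whole seconds.

    Hours are unbounded (totals such as ``1030:27:00`` are valid).
    """
    m = _DURATION_RE.match(text.strip())
    if m is None:
        raise ValueError(f"malformed duration in field {field_name!r}: {text!r}")
    hours, minutes = int(m.group(1)), int(m.group(2))
    seconds = int(m.group(3)) if m.group(3) is not None else 0
    return hours * 3600 + minutes * 60 + seconds


def format_duration(seconds: int) -> str:
    """Canonical ``H:MM:SS`` rendering of a non-negative duration."""
    if seconds < 0:
        raise ValueError("negative duration")
    h, rem = divmod(int(seconds), 3600)
    m, s = divmod(rem, 60)
    return f"{h}:{m:02d}:{s:02d}"


def parse_currency(text: str | None, field_name: str = "amount") -> int | None:
    """Parse a currency cell into euro-cents.

    ``None``, empty, em-dash and ``<x`` bound cells return ``None``
    (they count as zero in sums).  Thousands separators are accepted.
    """
    if text is None:
        return None
    t = str(text).strip().replace(",", "")
    if t in ("", "—", "-", "–", "n/a", "NA"):
        return None
    if t.startswith("<"):
        return None
    try:
        euros = float(t)
    except ValueError as exc:
        raise ValueError(f"malformed currency in field {field_name!r}: {text!r}") from exc
    if euros < 0:
        raise ValueError(f"negative currency in field {field_name!r}: {text!r}")
    return round(euros * 100)


@dataclass(frozen=True)
class CostStep:
    """One workflow step; monetary fields in euro-cents, times in seconds.

    ``None`` marks a cell that is absent in the source accounting.
    """

    name: str
    material_cost_per_sample: int | None = None
    total_material_cost: int | None = None
    labour_cost_per_sample: int | None = None
    time_per_sample: int | None = None
    total_time: int | None = None
    total_cost: int = 0

    def __post_init__(self):
        for f in ("material_cost_per_sample", "total_material_cost", "labour_cost_per_sample",
                  "time_per_sample", "total_time", "total_cost"):
            v = getattr(self, f)
            if v is not None and v < 0:
                raise ValueError(f"step {self.name!r}: {f} must be >= 0")


@dataclass
class CostLedger:
    steps: list[CostStep] = field(default_factory=list)
    n_samples: int = 1
    labour_rate_per_hour: float = 60.0
    fixed_overheads: dict[str, int] = field(default_factory=dict)  # name -> cents

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass(frozen=True)
class CostTotals:
    """Column-wise sums over a ledger, at cent / second precision."""

    material_per_sample_cents: int
    total_material_cents: int
    labour_per_sample_cents: int
    time_per_sample_seconds: int
    total_time_seconds: int
    grand_total_cents: int

    @property
    def material_per_sample(self) -> float:
        return self.material_per_sample_cents / 100

    @property
    def total_material(self) -> float:
        return self.total_material_cents / 100

    @property
    def labour_per_sample(self) -> float:
        return self.labour_per_sample_cents / 100

    @property
    def grand_total(self) -> float:
        return self.grand_total_cents / 100

    @property
    def per_sample_cost_cents(self) -> int:
        return self.material_per_sample_cents + self.labour_per_sample_cents

    @property
    def per_sample_cost_rounded(self) -> int:
        """Per-sample cost (material + labour) rounded to whole euros."""
        cents = self.per_sample_cost_cents
        return (cents + 50) // 100

    def as_dict(self) -> dict:
        return {
            "material_per_sample_eur": self.material_per_sample,
            "total_material_eur": self.total_material,
            "labour_per_sample_eur": self.labour_per_sample,
            "time_per_sample": format_duration(self.time_per_sample_seconds),
            "total_time": format_duration(self.total_time_seconds),
            "grand_total_eur": self.grand_total,
            "per_sample_cost_eur": self.per_sample_cost_rounded,
        }


def aggregate(ledger: CostLedger) -> CostTotals:
    """Column-wise sums over the steps, plus fixed overheads in the grand total."""

    def s(values: Iterable[int | None]) -> int:
        return sum(v for v in values if v is not None)

    steps = ledger.steps
    return CostTotals(
        material_per_sample_cents=s(st.material_cost_per_sample for st in steps),
        total_material_cents=s(st.total_material_cost for st in steps),
        labour_per_sample_cents=s(st.labour_cost_per_sample for st in steps),
        time_per_sample_seconds=s(st.time_per_sample for st in steps),
        total_time_seconds=s(st.total_time for st in steps),
        grand_total_cents=s(st.total_cost for st in steps) + sum(ledger.fixed_overheads.values()),
    )


_COLUMNS = [
    "step",
    "material_cost_per_sample",
    "total_material_cost",
    "labour_cost_per_sample",
    "time_per_sample",
    "total_time",
    "total_cost",
]


def load_steps_tsv(path: str | Path) -> list[CostStep]:
    """Read a steps TSV (columns as written by the reference file)."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    header = lines[0].rstrip("\n").split("\t")
    if header != _COLUMNS:
        raise ValueError(f"unexpected cost-step columns in {path}: {header}")
    steps = []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        cells = ln.split("\t")
        row = dict(zip(_COLUMNS, cells))
        name = row["step"]

        def dur(key: str) -> int | None:
            t = row.get(key, "").strip()
            if t in ("", "—", "-", "–"):
                return None
            return parse_duration(t, f"{name}.{key}")

        steps.append(
            CostStep(
                name=name,
                material_cost_per_sample=parse_currency(row["material_cost_per_sample"], f"{name}.material_cost_per_sample"),
                total_material_cost=parse_currency(row["total_material_cost"], f"{name}.total_material_cost"),
                labour_cost_per_sample=parse_currency(row["labour_cost_per_sample"], f"{name}.labour_cost_per_sample"),
                time_per_sample=dur("time_per_sample"),
                total_time=dur("total_time"),
                total_cost=parse_currency(row["total_cost"], f"{name}.total_cost") or 0,
            )
        )
    return steps


def reference_workflow_ledger(n_samples: int = 1815) -> CostLedger:
    """The packaged per-step accounting of the reference 1815-sample workflow."""
    with resources.as_file(resources.files("otucurate.data") / "reference_workflow_costs.tsv") as p:
        steps = load_steps_tsv(p)
    return CostLedger(steps=steps, n_samples=n_samples)
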