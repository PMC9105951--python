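"""Rendering of results into the published two-block table layout.

Levels print at one decimal; difference cells print as integers at or above
10 and at one decimal below, with half-up rounding (so 36.5 prints 37).
Rendering is pure: identical results yield byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import pandas as pd

from .psa import PsaSummary
from .scenarios import ComparisonTable

LOSS_CHANNELS = ("losses_cognitive", "losses_mortality", "losses_total")
DALY_CHANNELS = ("dalys_physical", "dalys_cognitive", "dalys_mortality", "dalys_total")

_HEADINGS = {
    "losses_cognitive": "Cognitive impairment",
    "losses_mortality": "Mortality",
    "losses_total": "Total",
    "dalys_physical": "Impaired physical activity",
    "dalys_cognitive": "Cognitive impairment",
    "dalys_mortality": "Mortality",
    "dalys_total": "Total",
}


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal half-up rounding of a float (36.5 -> 37, 0.6 -> 1)."""
    q = Decimal(1).scaleb(-decimals)
    # pre-round at 9 decimals to strip float noise before the display rounding
    d = Decimal(str(round(float(x), 9))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


def fmt_level(x: float) -> str:
    return f"{round_half_up(x, 1):.1f}"

def fmt_diff(x: float) -> str:
    if abs(x) >= 10:
        return f"{round_half_up(x, 0):.0f}"
    return f"{round_half_up(x, 1):.1f}"


def fmt_pct(x: float) -> str:
    return f"{round_half_up(x, 1):.1f}%"


def parse_cell(text: str) -> float:
    """Read a rendered number (optionally 'diff (pct%)') back to its value."""
    return float(text.strip().split(" ")[0].rstrip("%"))


def _block(table: ComparisonTable, channels: Sequence[str], current_label: str, other_label: str) -> list[str]:
    width = 28
    head = "".join(f"{_HEADINGS[c]:>{width}}" for c in channels)
    cur = "".join(f"{fmt_level(table.current.component(c)):>{width}}" for c in channels)
    oth = "".join(f"{fmt_level(table.other.component(c)):>{width}}" for c in channels)
    diff = "".join(
        f"{fmt_diff(table.abs_diff(c)) + ' (' + fmt_pct(table.pct_diff(c)) + ')':>{width}}"
        for c in channels
    )
    label_w = 52
    return [
        f"{'':{label_w}}{head}",
        f"{current_label:{label_w}}{cur}",
        f"{other_label:{label_w}}{oth}",
        f"{'Difference (%)':{label_w}}{diff}",
    ]


def render_tables(
    results: Sequence[ComparisonTable],
    psa: PsaSummary | None = None,
    current_label: str = "With current level of consumption and fortification",
) -> str:
    """Plain-text report of scenario comparisons in the two-block layout."""
    if not results:
        raise ValueError("no results to render")
    lines: list[str] = []
    for table in results:
        other_label = table.label or "Alternative scenario"
        lines.append(f"== {other_label} ==")
        lines.append("Production losses (millions of U.S. dollars)")
        lines += _block(table, LOSS_CHANNELS, current_label, other_label)
        lines.append("DALYs (thousands)")
        lines += _block(table, DALY_CHANNELS, current_label, other_label)
        lines.append("")
    if psa is not None:
        lines.append(f"Probabilistic sensitivity analysis ({psa.n_draws} runs, seed {psa.seed})")
        for channel in LOSS_CHANNELS + DALY_CHANNELS:
            lo, hi = psa.interval(channel)
            lines.append(
                f"{_HEADINGS[channel]} [{channel}]: mean {fmt_level(psa.mean(channel))}, "
                f"95% CI {fmt_level(lo)} to {fmt_level(hi)}"
            )
        lines.append("")
    return "\n".join(lines)


def comparison_frame(table: ComparisonTable) -> pd.DataFrame:
    """A comparison as a tidy frame (channel, current, other, diff, pct)."""
    rows = []
    for channel, cells in table.as_dict().items():
        rows.append({"channel": channel, **cells})
    return pd.DataFrame(rows).set_index("channel")


@dataclass(frozen=True)
class RunManifest:
    """Provenance record tying a report to its inputs and seeds."""

    config_digests: dict[str, str]
    seed: int | None
    scenarios: tuple[str, ...]
    timestamp: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    @staticmethod
    def digest(path: str | Path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]

    def to_json(self) -> str:
        return json.dumps(
            {
                "timestamp": self.timestamp,
                "config_digests": self.config_digests,
                "seed": self.seed,
                "scenarios": list(self.scenarios),
            },
            indent=2,
        )
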