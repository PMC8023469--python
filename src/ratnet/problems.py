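"""Remote Associates Test problems and empirical-hardness bookkeeping.

A RAT problem presents three stimulus words; the solver must produce the
single response word associatively related to all three.  Empirical
hardness ``H`` is the fraction of test subjects who solved the problem
within 15 seconds, so larger ``H`` means an easier problem.  Problems are
binned into three bands: hard ``[0, 0.32)``, medium ``[0.32, 0.64)`` and
easy ``[0.64, 1]`` (half-open convention so that every ``H`` falls in
exactly one band).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .network import normalize_word

__all__ = [
    "RATProblem",
    "HardnessCategory",
    "HARDNESS_BOUNDARIES",
    "categorize_hardness",
    "read_rat_table",
    "write_rat_table",
]

HardnessCategory = Literal["easy", "medium", "hard"]

#: (hard | medium, medium | easy) boundaries on H
HARDNESS_BOUNDARIES: tuple[float, float] = (0.32, 0.64)


@dataclass(frozen=True)
class RATProblem:
    """One RAT item: three distinct stimuli, one response, optional hardness."""

    id: str
    stimuli: tuple[str, str, str]
    response: str
    hardness: float | None = None

    def __post_init__(self):
        if len(self.stimuli) != 3:
            raise ValueError(f"problem {self.id!r}: exactly 3 stimuli required")
        if len(set(self.stimuli)) != 3:
            raise ValueError(f"problem {self.id!r}: stimuli must be distinct")
        if self.response in self.stimuli:
            raise ValueError(
                f"problem {self.id!r}: response {self.response!r} equals a stimulus"
            )
        if any(not w for w in (*self.stimuli, self.response)):
            raise ValueError(f"problem {self.id!r}: empty word label")
        if self.hardness is not None and not (0.0 <= self.hardness <= 1.0):
            raise ValueError(
                f"problem {self.id!r}: hardness {self.hardness} outside [0, 1]"
            )

    @property
    def words(self) -> tuple[str, str, str, str]:
        return (*self.stimuli, self.response)


def categorize_hardness(hardness: float) -> HardnessCategory:
    """Map empirical hardness ``H`` to its category band."""
    if not (0.0 <= hardness <= 1.0):
        raise ValueError(f"hardness {hardness} outside [0, 1]")
    lo, hi = HARDNESS_BOUNDARIES
    if hardness < lo:
        return "hard"
    if hardness < hi:
        return "medium"
    return "easy"


def read_rat_table(path) -> list[RATProblem]:
    """Read a RAT problem table.

    CSV with header ``id,stim1,stim2,stim3,response[,hardness]`` (UTF-8).
    Word labels are lowercased and stripped so they join against network
    vocabularies; duplicate ids, invalid hardness values and
    stimulus/response collisions are errors.
    """
    problems: list[RATProblem] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "stim1", "stim2", "stim3", "response"}
        fields = set(reader.fieldnames or [])
        if not required <= fields:
            raise ValueError(
                f"{path}: header must contain {sorted(required)}, got {reader.fieldnames}"
            )
        for row in reader:
            pid = str(row["id"]).strip()
            if pid in seen:
                raise ValueError(f"{path}: duplicate problem id {pid!r}")
            seen.add(pid)
            hardness = None
            raw_h = (row.get("hardness") or "").strip()
            if raw_h:
                hardness = float(raw_h)
            problems.append(
                RATProblem(
                    id=pid,
                    stimuli=(
                        normalize_word(row["stim1"]),
                        normalize_word(row["stim2"]),
                        normalize_word(row["stim3"]),
                    ),
                    response=normalize_word(row["response"]),
                    hardness=hardness,
                )
            )
    return problems


def write_rat_table(problems: Iterable[RATProblem], path) -> None:
    """Write problems in the CSV format accepted by :func:`read_rat_table`."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "stim1", "stim2", "stim3", "response", "hardness"])
        for p in problems:
            writer.writerow(
                [p.id, *p.stimuli, p.response,
                 "" if p.hardness is None else f"{p.hardness:.17g}"]
            )
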