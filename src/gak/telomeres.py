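"""Telomeric repeat end-calling for assembly scaffolds.

A scaffold end is called telomeric when at least `min_copies` consecutive
copies of the telomere unit occur within a terminal window. The unit is
read 5'->3' on the G-rich strand, so the 3' end of a scaffold carries
forward units (TTAGGG by default) and the 5' end carries their reverse
complement (CCCTAA). Scaffolds with both ends called are complete
chromosome candidates.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable

from .io_formats import GenomeRecord
from .ssr import reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_UNIT = "TTAGGG"


@dataclass(frozen=True)
class TelomereCall:
    scaffold_id: str
    end5: bool
    end3: bool
    copies5: int
    copies3: int

    @property
    def n_ends(self) -> int:
        return int(self.end5) + int(self.end3)


def _longest_tandem_run(window: str, unit: str) -> int:
    """Longest count of consecutive unit copies anywhere in the window."""
    best = 0
    for match in re.finditer(f"(?:{re.escape(unit)})+", window):
        best = max(best, (match.end() - match.start()) // len(unit))
    return best


def find_telomeres(record: GenomeRecord, unit: str = DEFAULT_UNIT,
                   min_copies: int = 5, window: int = 200) -> TelomereCall:
    """Call telomeric arrays at both ends of one scaffold.

    Copy counts are the longest consecutive run of the unit (reverse
    complement at the 5' end) within the terminal window; a single
    interrupting base breaks a run.
    """
    if any(ch not in "ACGT" for ch in unit) or not unit:
        raise ValueError(f"unit must be non-empty over ACGT, got {unit!r}")
    if window < len(unit) * min_copies:
        raise ValueError("window shorter than min_copies telomere units")
    if record.length < window:
        logger.warning("scaffold %s shorter than window; truncating",
                       record.scaffold_id)
        window = record.length
    head = record.sequence[:window]
    tail = record.sequence[-window:]
    copies5 = _longest_tandem_run(head, reverse_complement(unit))
    copies3 = _longest_tandem_run(tail, unit)
    return TelomereCall(
        scaffold_id=record.scaffold_id,
        end5=copies5 >= min_copies,
        end3=copies3 >= min_copies,
        copies5=copies5,
        copies3=copies3,
    )


def telomere_summary(calls: Iterable[TelomereCall]) -> dict[str, int]:
    """Partition scaffolds into complete / one_end / none telomere classes."""
    seen: set[str] = set()
    summary = {"complete": 0, "one_end": 0, "none": 0}
    for call in calls:
        if call.scaffold_id in seen:
            raise ValueError(f"duplicate scaffold in calls: {call.scaffold_id!r}")
        seen.add(call.scaffold_id)
        if call.n_ends == 2:
            summary["complete"] += 1
        elif call.n_ends == 1:
            summary["one_end"] += 1
        else:
            summary["none"] += 1
    return summary
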