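"""Accounting of oracle (QM-equivalent) minimizations by purpose.

In production the constrained minimizations dominate the cost of building
a reference database, so every build, refinement and rebase operation
increments this ledger.  Counts never decrease.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = ["CallLedger"]


@dataclass
class CallLedger:
    """Counts of oracle minimizations keyed by purpose.

    Conventional purposes: ``vacuo``, ``fit:group<g>``, ``adaptive:group<g>``,
    ``rebase``.  ``total`` is always the sum over purposes.
    """

    counts: dict = field(default_factory=dict)

    def add(self, purpose: str, n: int = 1) -> None:
        if n < 0:
            raise ValueError("ledger counts never decrease")
        self.counts[purpose] = self.counts.get(purpose, 0) + int(n)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def get(self, purpose: str) -> int:
        return self.counts.get(purpose, 0)

    def merge(self, other: "CallLedger") -> None:
        for k, v in other.counts.items():
            self.add(k, v)

    def copy(self) -> "CallLedger":
        return CallLedger(counts=dict(self.counts))

    def to_dict(self) -> dict:
        return {"counts": dict(self.counts), "total": self.total}

    @classmethod
    def from_dict(cls, d: Mapping) -> "CallLedger":
        return cls(counts={str(k): int(v) for k, v in d["counts"].items()})

    def to_tsv(self) -> str:
        lines = ["purpose\tcalls"]
        for k in sorted(self.counts):
            lines.append(f"{k}\t{self.counts[k]}")
        lines.append(f"total\t{self.total}")
        return "\n".join(lines) + "\n"

    def __str__(self) -> str:
        body = ", ".join(f"{k}={v}" for k, v in sorted(self.counts.items()))
        return f"CallLedger({body}, total={self.total})"
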