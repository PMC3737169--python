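"""Genetic maps: physical (bp) <-> genetic (cM) coordinate interpolation.

A map is a set of chromosome arms, each carrying a monotone table of
(position_bp, position_cM) anchor points.  Positions between anchors are
linearly interpolated, which is all the downstream machinery needs: the scan
smoother and the two-position scans work in cM, segment bookkeeping works in
bp.  Arms named like ``2L``/``2R`` are treated as two arms of one chromosome
and can be concatenated on the cM scale (centromere-spanning peaks).
"""

from __future__ import annotations

import numpy as np

__all__ = ["GeneticMap", "chromosome_of"]


def chromosome_of(arm: str) -> str:
    """Chromosome name an arm belongs to (``'3L'`` -> ``'3'``, ``'X'`` -> ``'X'``)."""
    if len(arm) > 1 and arm[-1] in ("L", "R"):
        return arm[:-1]
    return arm


class GeneticMap:
    """Piecewise-linear genetic map over named chromosome arms.

    Parameters
    ----------
    arms
        Mapping arm name -> array of shape (k, 2) with columns
        (position_bp, position_cM).  bp must be strictly increasing and cM
        non-decreasing; the first anchor defines the arm start (usually 0)
        and the last anchor the arm length.
    """

    def __init__(self, arms: dict[str, np.ndarray]):
        self.arms: dict[str, np.ndarray] = {}
        for name, table in arms.items():
            t = np.asarray(table, dtype=float)
            if t.ndim != 2 or t.shape[1] != 2 or t.shape[0] < 2:
                raise ValueError(f"arm {name!r}: need a (k>=2, 2) anchor table")
            if not np.all(np.diff(t[:, 0]) > 0):
                raise ValueError(f"arm {name!r}: bp positions must be strictly increasing")
            if not np.all(np.diff(t[:, 1]) >= 0):
                raise ValueError(f"arm {name!r}: cM must be non-decreasing in bp")
            self.arms[name] = t

    @classmethod
    def uniform(cls, arm_lengths_bp: dict[str, int], cm_per_mb: float = 2.0) -> "GeneticMap":
        """Constant-rate map (default 2 cM/Mb, a typical fly euchromatic rate)."""
        return cls(
            {
                name: np.array([[0.0, 0.0], [length, length / 1e6 * cm_per_mb]])
                for name, length in arm_lengths_bp.items()
            }
        )

    @property
    def arm_names(self) -> list[str]:
        return list(self.arms)

    def arm_length_bp(self, arm: str) -> int:
        return int(self.arms[arm][-1, 0])

    def arm_length_cm(self, arm: str) -> float:
        return float(self.arms[arm][-1, 1] - self.arms[arm][0, 1])

    def bp_to_cm(self, arm: str, bp):
        t = self.arms[arm]
        return np.interp(bp, t[:, 0], t[:, 1])

    def cm_to_bp(self, arm: str, cm):
        t = self.arms[arm]
        return np.interp(cm, t[:, 1], t[:, 0])

    def total_length_morgans(self) -> float:
        return sum(self.arm_length_cm(a) for a in self.arms) / 100.0
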