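"""Post-processing of coalescent-HMM per-site posteriors.

A four-taxon coalescent HMM emits, per alignment site, posterior
probabilities over four hidden states: shallow coalescence matching
the species tree (S), deep coalescence matching the species tree
(D1), and the two discordant deep-coalescence states (D2, D3). This
module never runs the HMM; it consumes a TSV of posteriors
(chrom, pos, pS, pD1, pD2, pD3), assigns each site to its maximum
a-posteriori state, tiles sites into fixed windows (100 kb by
default), and summarizes per-window topology support, ILS level, and
MSC admissibility.

Under the multispecies coalescent the total probability of the two
discordant quartet topologies is 2/3 * exp(-T) for an internal branch
of T coalescent units, so no MSC history can push the discordant
fraction above 2/3 (the T -> 0 hard-polytomy limit). A region whose
discordant-site fraction exceeds that bound cannot be explained by
ILS alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "STATES",
    "read_posteriors",
    "assign_states",
    "window_fractions",
    "ils_level",
    "msc_discordance_bound",
    "msc_admissible",
]

#: state order; ties in the per-site argmax break in this order
STATES = ("S", "D1", "D2", "D3")

PROB_SUM_TOL = 1e-6


def read_posteriors(path) -> pd.DataFrame:
    """Read a TSV of (chrom, pos, pS, pD1, pD2, pD3)."""
    df = pd.read_csv(path, sep="\t")
    expected = ["chrom", "pos", "pS", "pD1", "pD2", "pD3"]
    missing = set(expected) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for chrom, grp in df.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            i = int(np.flatnonzero(np.diff(pos) <= 0)[0])
            raise ValueError(
                f"{path}: positions not strictly increasing on {chrom} "
                f"near pos={pos[i + 1]}"
            )
    return df


def assign_states(probs: np.ndarray) -> np.ndarray:
    """Maximum-a-posteriori state index per site.

    ``probs`` has one row per site with columns in STATES order; each
    row must sum to 1 within tolerance. Ties break toward the earlier
    state in STATES (S > D1 > D2 > D3).
    """
    probs = np.asarray(probs, dtype=float)
    sums = probs.sum(axis=1)
    bad = np.abs(sums - 1.0) > PROB_SUM_TOL
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"site {i}: posterior probabilities sum to {sums[i]:.6g}, not 1"
        )
    # np.argmax returns the first index at the maximum, which is
    # exactly the documented tie-break order
    return np.argmax(probs, axis=1)


@dataclass(frozen=True)
class WindowFractions:
    """Site-state tallies and support fractions for one window."""

    start: int
    end: int
    counts: tuple[int, int, int, int]  # S, D1, D2, D3

    @property
    def total(self) -> int:
        return sum(self.counts)

    @property
    def main(self) -> float:
        s, d1, d2, d3 = self.counts
        return (s + d1) / self.total

    @property
    def alt2(self) -> float:
        return self.counts[2] / self.total

    @property
    def alt3(self) -> float:
        return self.counts[3] / self.total

    @property
    def shallow(self) -> float:
        return self.counts[0] / self.total

    @property
    def deep1(self) -> float:
        return self.counts[1] / self.total


def window_fractions(
    labels: np.ndarray, coords: np.ndarray, window_bp: int = 100_000
) -> pd.DataFrame:
    """Tile sites into fixed non-overlapping windows and count states.

    Windows start at coordinate 0 in steps of ``window_bp``; empty
    windows are omitted. Fractions: main = (S+D1)/total,
    alt2 = D2/total, alt3 = D3/total, plus shallow and deep-but-
    concordant components of main.
    """
    labels = np.asarray(labels)
    coords = np.asarray(coords)
    if len(labels) != len(coords):
        raise ValueError("labels and coords must align")
    win = coords // window_bp
    rows = []
    for w in np.unique(win):
        sel = labels[win == w]
        counts = np.bincount(sel, minlength=4)
        total = int(counts.sum())
        rows.append(
            {
                "start": int(w) * window_bp,
                "end": (int(w) + 1) * window_bp,
                "n_sites": total,
                "S": int(counts[0]),
                "D1": int(counts[1]),
                "D2": int(counts[2]),
                "D3": int(counts[3]),
                "main": (counts[0] + counts[1]) / total,
                "alt2": counts[2] / total,
                "alt3": counts[3] / total,
                "shallow": counts[0] / total,
                "deep1": counts[1] / total,
            }
        )
    return pd.DataFrame(rows)


def ils_level(counts) -> tuple[float, float] | None:
    """(deep_fraction, discordant_fraction) from (S, D1, D2, D3) counts.

    deep_fraction = (D1+D2+D3)/total estimates how often coalescence
    predates the relevant speciation; discordant_fraction =
    (D2+D3)/total is the share of sites whose topology conflicts with
    the assumed species tree. None when there are no sites.
    """
    s, d1, d2, d3 = (int(c) for c in counts)
    total = s + d1 + d2 + d3
    if total == 0:
        return None
    return ((d1 + d2 + d3) / total, (d2 + d3) / total)


def msc_discordance_bound(T: float = 0.0) -> float:
    """Total probability of the two discordant quartet topologies
    under the MSC for an internal branch of T coalescent units:
    2 * (1/3) * exp(-T). The supremum over T >= 0 (at T = 0) is the
    admissibility bound 2/3."""
    if T < 0:
        raise ValueError("branch length T must be >= 0")
    return 2.0 * (1.0 / 3.0) * math.exp(-T)


def msc_admissible(discordant_fraction: float) -> bool:
    """True when the discordant-site fraction can be explained by ILS
    alone, i.e. does not exceed the T -> 0 MSC bound."""
    if not 0.0 <= discordant_fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    return discordant_fraction <= msc_discordance_bound(0.0)
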