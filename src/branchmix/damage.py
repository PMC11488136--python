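"""Position-dependent post-mortem deamination profiles.

Ancient DNA carries cytosine deamination that reads as C->T near the 5' end
of a fragment and (on double-stranded libraries) as G->A near the 3' end,
with rates decaying into the fragment interior. A profile stores one rate
array per channel, anchored at its end, plus a flat residual rate used
beyond the tabulated positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hky import BASE_INDEX


class DamageError(ValueError):
    pass


@dataclass
class DamageProfile:
    ct5: np.ndarray  # C->T rate at position p from the 5' end
    ga3: np.ndarray  # G->A rate at position p from the 3' end
    residual_ct: float | None = None  # beyond the table; defaults to last entry
    residual_ga: float | None = None

    def __post_init__(self):
        self.ct5 = np.atleast_1d(np.asarray(self.ct5, dtype=float))
        self.ga3 = np.atleast_1d(np.asarray(self.ga3, dtype=float))
        if self.ct5.size < 1 or self.ga3.size < 1:
            raise DamageError("profiles need at least one position")
        if self.residual_ct is None:
            self.residual_ct = float(self.ct5[-1])
        if self.residual_ga is None:
            self.residual_ga = float(self.ga3[-1])
        allr = np.concatenate([self.ct5, self.ga3, [self.residual_ct, self.residual_ga]])
        if np.any(allr < 0) or np.any(allr > 1):
            raise DamageError("damage rates must lie in [0, 1]")

    def rate_ct(self, pos5: int) -> float:
        if pos5 < 0:
            raise DamageError("positions must be non-negative")
        return float(self.ct5[pos5]) if pos5 < self.ct5.size else self.residual_ct

    def rate_ga(self, pos3: int) -> float:
        if pos3 < 0:
            raise DamageError("positions must be non-negative")
        return float(self.ga3[pos3]) if pos3 < self.ga3.size else self.residual_ga

    def matrix(self, pos5: int, pos3: int) -> np.ndarray:
        """Row-stochastic 4x4 matrix P(observed base | source base) at this
        pair of end distances (rows/cols in A,C,G,T order)."""
        d5, d3 = self.rate_ct(pos5), self.rate_ga(pos3)
        M = np.eye(4)
        A, C, G, T = (BASE_INDEX[b] for b in "ACGT")
        M[C, C] = 1.0 - d5
        M[C, T] = d5
        M[G, G] = 1.0 - d3
        M[G, A] = d3
        return M


def delta_at(profile: DamageProfile, pos5: int, pos3: int, source_base: str, observed_base: str) -> float:
    """Probability of observing `observed_base` given `source_base` under
    deamination alone, at the stated distances from the fragment ends."""
    s, o = source_base.upper(), observed_base.upper()
    if s not in BASE_INDEX or o not in BASE_INDEX:
        raise DamageError(f"bases must be in ACGT, got {source_base}->{observed_base}")
    return float(profile.matrix(pos5, pos3)[BASE_INDEX[s], BASE_INDEX[o]])


def uniform_profile(delta: float) -> DamageProfile:
    """Constant-rate profile; uniform_profile(0) means no damage."""
    if not (0.0 <= delta <= 1.0):
        raise DamageError("delta must lie in [0, 1]")
    return DamageProfile(np.array([delta]), np.array([delta]), delta, delta)


def zero_profile() -> DamageProfile:
    return uniform_profile(0.0)


_CT_NAMES = {"C>T", "C->T", "CT", "C2T", "5PC>T"}
_GA_NAMES = {"G>A", "G->A", "GA", "G2A", "3PG>A"}


def _find_column(df: pd.DataFrame, wanted: set[str], what: str) -> str:
    for col in df.columns:
        if str(col).strip().upper().replace(" ", "") in wanted:
            return col
    raise DamageError(f"no {what} column found among {list(df.columns)}")


def read_damage_profile(path) -> DamageProfile:
    """Read a TSV damage table: rows are positions, columns include at least
    a C>T and a G>A rate. 12-substitution (bam2prof-style) tables are
    accepted; the extra columns are ignored. Row p supplies the C->T rate at
    position p from the 5' end and the G->A rate at position p from the 3' end."""
    df = pd.read_csv(path, sep="\t", comment=None)
    if df.shape[0] < 1:
        raise DamageError(f"empty damage table {path}")
    ct = df[_find_column(df, _CT_NAMES, "C>T")].to_numpy(dtype=float)
    ga = df[_find_column(df, _GA_NAMES, "G>A")].to_numpy(dtype=float)
    return DamageProfile(ct, ga)


def read_damage_profiles(path5, path3) -> DamageProfile:
    """Two-file variant: C>T rates from the 5'-anchored table, G>A rates
    from the 3'-anchored table (bam2prof 5p.prof / 3p.prof convention)."""
    p5 = read_damage_profile(path5)
    p3 = read_damage_profile(path3)
    return DamageProfile(p5.ct5, p3.ga3)


def write_damage_profile(profile: DamageProfile, path) -> None:
    n = max(profile.ct5.size, profile.ga3.size)
    ct = np.array([profile.rate_ct(i) for i in range(n)])
    ga = np.array([profile.rate_ga(i) for i in range(n)])
    pd.DataFrame({"pos": np.arange(n), "C>T": ct, "G>A": ga}).to_csv(path, sep="\t", index=False)
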