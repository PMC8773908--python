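"""Two-channel colocalization and RNA-class calls.

A full-length linear transcript carries binding sites for both probe sets
and therefore produces a spot in each channel at (nearly) the same 3D
position; a circRNA binds only the PC set, and a degraded linear fragment
retaining only the PL region binds only the PL set. Classification is
purely geometric: PL and PC spots within 250 nm (3D Euclidean, inclusive)
are paired one-to-one, greedily by ascending distance; paired spots are
full-length linear molecules (reported at the pair midpoint), unmatched PC
spots are circular, unmatched PL spots are fragments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .detect import Spot

__all__ = [
    "MatchResult",
    "ClassifiedSpots",
    "match_spots",
    "classify",
    "multiplex_counts",
    "DEFAULT_RADIUS_NM",
]

DEFAULT_RADIUS_NM = 250.0

_POSITION_COLUMNS = ["z_nm", "y_nm", "x_nm"]


def _positions(spots) -> np.ndarray:
    """Coerce a spot list / DataFrame / array to an (n, 3) nm array."""
    if isinstance(spots, pd.DataFrame):
        if len(spots) == 0:
            return np.empty((0, 3))
        return spots[_POSITION_COLUMNS].to_numpy(dtype=float)
    if len(spots) == 0:
        return np.empty((0, 3))
    if isinstance(spots[0], Spot):
        return np.array([s.position_nm for s in spots], dtype=float)
    return np.asarray(spots, dtype=float).reshape(len(spots), 3)


@dataclass(frozen=True)
class MatchResult:
    pairs: tuple[tuple[int, int, float], ...]  # (pl_index, pc_index, distance_nm)
    unmatched_pl: tuple[int, ...]
    unmatched_pc: tuple[int, ...]
    radius_nm: float
    n_pl: int
    n_pc: int
    one_to_one: bool = True

    def __post_init__(self) -> None:
        pl_used = [i for i, _, _ in self.pairs]
        pc_used = [j for _, j, _ in self.pairs]
        if self.one_to_one:
            if len(set(pl_used)) != len(pl_used) or len(set(pc_used)) != len(pc_used):
                raise ValueError("matching is not one-to-one")
        if any(d > self.radius_nm for _, _, d in self.pairs):
            raise ValueError("pair distance exceeds radius")
        if sorted(set(pl_used) | set(self.unmatched_pl)) != list(range(self.n_pl)):
            raise ValueError("PL indices do not partition the input")
        if sorted(set(pc_used) | set(self.unmatched_pc)) != list(range(self.n_pc)):
            raise ValueError("PC indices do not partition the input")


def match_spots(
    pl_spots,
    pc_spots,
    radius_nm: float = DEFAULT_RADIUS_NM,
    one_to_one: bool = True,
    in_plane: bool = False,
) -> MatchResult:
    """Pair PL and PC spots within ``radius_nm`` (inclusive).

    Candidate cross-channel pairs are sorted by ascending distance (ties by
    lower PL index, then lower PC index) and accepted greedily while both
    endpoints are free. With ``one_to_one=False`` every spot simply takes
    its nearest in-radius counterpart, allowing many-to-one pairings (the
    alternative reading of the counterpart rule). ``in_plane`` restricts
    the distance to the lateral (y, x) plane.
    """
    if radius_nm < 0:
        raise ValueError("radius_nm must be >= 0")
    pl = _positions(pl_spots)
    pc = _positions(pc_spots)
    if in_plane:
        pl, pc = pl[:, 1:], pc[:, 1:]
    n_pl, n_pc = len(pl), len(pc)
    if n_pl == 0 or n_pc == 0:
        return MatchResult((), tuple(range(n_pl)), tuple(range(n_pc)),
                           radius_nm, n_pl, n_pc)
    tree = cKDTree(pc)
    neighbors = tree.query_ball_point(pl, r=radius_nm)
    candidates = [
        (float(np.linalg.norm(pl[i] - pc[j])), i, j)
        for i, js in enumerate(neighbors)
        for j in js
    ]
    candidates.sort()
    pairs: list[tuple[int, int, float]] = []
    if one_to_one:
        pl_free = np.ones(n_pl, dtype=bool)
        pc_free = np.ones(n_pc, dtype=bool)
        for d, i, j in candidates:
            if pl_free[i] and pc_free[j]:
                pairs.append((i, j, d))
                pl_free[i] = False
                pc_free[j] = False
    else:
        # nearest counterpart per spot, reuse allowed on the other side
        best_for_pl: dict[int, tuple[float, int]] = {}
        for d, i, j in candidates:
            if i not in best_for_pl:
                best_for_pl[i] = (d, j)
        pairs = [(i, j, d) for i, (d, j) in sorted(best_for_pl.items())]
    matched_pl = {i for i, _, _ in pairs}
    matched_pc = {j for _, j, _ in pairs}
    return MatchResult(
        pairs=tuple(pairs),
        unmatched_pl=tuple(i for i in range(n_pl) if i not in matched_pl),
        unmatched_pc=tuple(j for j in range(n_pc) if j not in matched_pc),
        radius_nm=radius_nm,
        n_pl=n_pl,
        n_pc=n_pc,
        one_to_one=one_to_one,
    )


@dataclass
class ClassifiedSpots:
    """Per-class spot tables; linear spots sit at the midpoint of their pair."""

    linear: pd.DataFrame
    circular: pd.DataFrame
    fragment: pd.DataFrame

    @property
    def counts(self) -> dict[str, int]:
        return {
            "linear": len(self.linear),
            "circular": len(self.circular),
            "fragment": len(self.fragment),
        }

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for cls in ("linear", "circular", "fragment"):
            sub = getattr(self, cls).copy()
            sub.insert(0, "class", cls)
            frames.append(sub)
        return pd.concat(frames, ignore_index=True)


def classify(match: MatchResult, pl_spots, pc_spots) -> ClassifiedSpots:
    """Turn a MatchResult into linear / circular / fragment spot tables.

    Conservation identities hold by construction:
    ``|linear| + |circular| = n_pc`` and ``|linear| + |fragment| = n_pl``.
    """
    pl = _positions(pl_spots)
    pc = _positions(pc_spots)
    if len(pl) != match.n_pl or len(pc) != match.n_pc:
        raise ValueError(
            f"spot lists ({len(pl)} PL, {len(pc)} PC) do not match the "
            f"MatchResult ({match.n_pl} PL, {match.n_pc} PC)"
        )

    def _frame(points: np.ndarray, distances=None) -> pd.DataFrame:
        out = pd.DataFrame(points, columns=_POSITION_COLUMNS)
        out["pair_distance_nm"] = distances if distances is not None else np.nan
        return out

    if match.pairs:
        mid = np.array([(pl[i] + pc[j]) / 2.0 for i, j, _ in match.pairs])
        dists = [d for _, _, d in match.pairs]
    else:
        mid, dists = np.empty((0, 3)), []
    return ClassifiedSpots(
        linear=_frame(mid, dists),
        circular=_frame(pc[list(match.unmatched_pc)]),
        fragment=_frame(pl[list(match.unmatched_pl)]),
    )


def multiplex_counts(
    pc_spot_lists: dict[str, object],
    radius_nm: float = DEFAULT_RADIUS_NM,
    check_bleedthrough: bool = True,
) -> tuple[dict[str, int], list[tuple[str, str, int]]]:
    """Independent per-channel circRNA counts for RNase-R-multiplexed samples.

    Each channel is a distinct circRNA, so no cross-channel matching is
    performed; counts are simply the spot numbers. Optionally, pairs of
    spots within the radius across two circRNA channels are tallied as
    bleed-through warnings (they should be rare for spectrally distinct
    fluorophores).
    """
    counts = {name: len(_positions(spots)) for name, spots in pc_spot_lists.items()}
    warnings_out: list[tuple[str, str, int]] = []
    if check_bleedthrough:
        names = list(pc_spot_lists)
        for a_idx in range(len(names)):
            for b_idx in range(a_idx + 1, len(names)):
                a, b = names[a_idx], names[b_idx]
                m = match_spots(
                    pc_spot_lists[a], pc_spot_lists[b], radius_nm=radius_nm
                )
                if m.pairs:
                    warnings_out.append((a, b, len(m.pairs)))
    return counts, warnings_out
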