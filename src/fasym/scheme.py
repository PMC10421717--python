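"""Landmark schemes for object symmetry.

A :class:`LandmarkScheme` records which landmark indices form bilateral
(left/right) pairs and which lie on the midline plane.  It is the single
source of truth for the reflection-with-relabelling operation that object
symmetry analysis is built on, and for the shape-space dimensions

* symmetric component:   ``d_sym  = 3*p + 2*u - 4``
* asymmetric component:  ``d_asym = 3*p + u - 3``

for ``p`` bilateral pairs and ``u`` midline landmarks in three dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class LandmarkScheme:
    """Assignment of landmark indices to bilateral pairs and midline points.

    Parameters
    ----------
    n_landmarks
        Total number of landmarks (``2*p + u``).
    pairs
        ``(left, right)`` index tuples, 0-based.
    midline
        Indices of unpaired midline landmarks, 0-based.
    dimension
        Spatial dimension; only 3 is supported by the analysis.
    """

    n_landmarks: int
    pairs: tuple[tuple[int, int], ...]
    midline: tuple[int, ...]
    dimension: int = 3

    def __post_init__(self) -> None:
        pairs = tuple((int(a), int(b)) for a, b in self.pairs)
        midline = tuple(int(i) for i in self.midline)
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "midline", midline)
        used = [i for ab in pairs for i in ab] + list(midline)
        if len(set(used)) != len(used):
            raise ValueError("landmark index appears in more than one role")
        if sorted(used) != list(range(self.n_landmarks)):
            raise ValueError(
                f"pair/midline indices must cover 0..{self.n_landmarks - 1} "
                f"exactly; got {sorted(used)}"
            )
        if 2 * self.n_pairs + self.n_midline != self.n_landmarks:
            raise ValueError("n_landmarks != 2*p + u")
        if self.dimension != 3:
            raise ValueError("only 3-D landmark data is supported")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_midline(self) -> int:
        return len(self.midline)

    @property
    def d_sym(self) -> int:
        """Dimension of the symmetric shape subspace after superimposition."""
        return 3 * self.n_pairs + 2 * self.n_midline - 4

    @property
    def d_asym(self) -> int:
        """Dimension of the asymmetric shape subspace after superimposition."""
        return 3 * self.n_pairs + self.n_midline - 3

    def relabel_permutation(self) -> list[int]:
        """Row permutation that swaps each left landmark with its right partner."""
        perm = list(range(self.n_landmarks))
        for left, right in self.pairs:
            perm[left], perm[right] = right, left
        return perm


def macaque_cranium_scheme() -> LandmarkScheme:
    """The 34-landmark cranial scheme: 13 bilateral pairs plus 8 midline points.

    Pairs and midline follow the standard craniometric protocol used for the
    rhesus-macaque crania this package was written around (1-based landmark
    numbers in the protocol: pairs 5/6, 7/8, 9/10, 11/12, 13/14, 15/18, 16/19,
    17/20, 25/26, 27/28, 29/30, 31/32, 33/34; midline 1-4, 21-24).  Indices
    here are 0-based.
    """
    pairs_1based = [
        (5, 6), (7, 8), (9, 10), (11, 12), (13, 14),
        (15, 18), (16, 19), (17, 20),
        (25, 26), (27, 28), (29, 30), (31, 32), (33, 34),
    ]
    midline_1based = [1, 2, 3, 4, 21, 22, 23, 24]
    return LandmarkScheme(
        n_landmarks=34,
        pairs=tuple((a - 1, b - 1) for a, b in pairs_1based),
        midline=tuple(i - 1 for i in midline_1based),
    )
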