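"""Geometry of the two-array replication-timing reporter locus.

The assay marks two chromosomal loci with tandem bacterial operator arrays —
a *lacO* array bound by lacI-GFP and a *tetO* array bound by tetR-tdTomato —
inserted downstream of an early-firing origin (ARS413 on yeast chromosome
IV).  A replication fork travelling from the origin duplicates the first
array, then the inter-array interval (optionally containing a G-quadruplex
obstacle), then the second array.  The time delay between the two intensity
doublings measures the replication time of the interval between the array
*midpoints*, so the relevant distance is the inner spacing plus half an
array length on each side.

Two stock layouts are provided:

``nominal_layout``
    10 kb arrays with inner edges 20 kb apart — the 30 kb mid-to-mid
    convention used for reporting rates.
``chr4_layout``
    The printed chromosome IV insertion coordinates (lacO at 332,960, the
    G4 obstacle at 344,119, tetO at 352,560).

Genomic coordinates are 1-based base pairs as printed; array lengths are in
kb.  The insertion coordinate is taken as the *inner* edge of each array
(array 1 extends upstream, array 2 downstream).
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class LocusLayout:
    """Positions of the origin, the two operator arrays and an optional obstacle.

    Parameters
    ----------
    array1_pos, array2_pos:
        Insertion coordinates (bp) of the proximal (lacO) and distal (tetO)
        arrays; interpreted as the inner edges of the arrays.
    array_len_kb:
        Length of each operator array in kb (both arrays equal).
    origin_pos:
        Coordinate (bp) of the replication origin, upstream of array 1, or
        ``None`` if firing geometry is irrelevant.
    obstacle_pos:
        Coordinate (bp) of the inserted G4 motif, or ``None`` for no insert.
    obstacle_strand:
        Which template strand carries the G4 relative to fork direction,
        ``"lagging"`` or ``"leading"``.
    """

    array1_pos: int
    array2_pos: int
    array_len_kb: float = 10.0
    origin_pos: int | None = None
    obstacle_pos: int | None = None
    obstacle_strand: str = "lagging"

    def __post_init__(self) -> None:
        if self.array_len_kb < 0:
            raise ValueError("array_len_kb must be >= 0")
        if self.array2_pos <= self.array1_pos:
            raise ValueError("array2_pos must lie beyond array1_pos")
        if self.obstacle_pos is not None and not (
            self.array1_pos < self.obstacle_pos < self.array2_pos
        ):
            raise ValueError("obstacle must lie strictly between the arrays")
        if self.obstacle_strand not in ("lagging", "leading"):
            raise ValueError("obstacle_strand must be 'lagging' or 'leading'")
        if self.origin_pos is not None and self.origin_pos >= self.array1_pos:
            raise ValueError("origin must lie upstream of array 1")

    @property
    def inner_spacing_kb(self) -> float:
        return (self.array2_pos - self.array1_pos) / 1000.0

    @property
    def mid_to_mid_kb(self) -> float:
        """Distance between array midpoints: inner spacing + 2 x (array_len/2)."""
        return self.inner_spacing_kb + self.array_len_kb

    @property
    def origin_to_array1_mid_kb(self) -> float:
        """Distance from origin to the midpoint of array 1 (0 if no origin)."""
        if self.origin_pos is None:
            return 0.0
        return (self.array1_pos - self.origin_pos) / 1000.0 - self.array_len_kb / 2.0


def _display_kb(x: float) -> float:
    """Truncate toward zero to 0.1 kb for display (8.441 -> 8.4)."""
    return math.trunc(round(x * 10.0, 6)) / 10.0


@dataclass(frozen=True)
class LocusGeometry:
    """Inter-point distances of a layout.

    The headline attributes are truncated toward zero to 0.1 kb, matching how
    such distances are conventionally printed; the exact values are retained
    in ``exact`` (a dict keyed by the same names).
    """

    mid_to_mid_kb: float
    array1_to_obstacle_kb: float | None
    obstacle_to_array2_kb: float | None
    exact: dict


def locus_geometry(layout: LocusLayout) -> LocusGeometry:
    """Compute mid-to-mid and obstacle distances for a reporter layout.

    Examples
    --------
    >>> locus_geometry(nominal_layout()).mid_to_mid_kb
    30.0
    >>> locus_geometry(chr4_layout()).obstacle_to_array2_kb
    8.4
    """
    mid = layout.mid_to_mid_kb
    if layout.obstacle_pos is not None:
        a1_obs = (layout.obstacle_pos - layout.array1_pos) / 1000.0
        obs_a2 = (layout.array2_pos - layout.obstacle_pos) / 1000.0
    else:
        a1_obs = obs_a2 = None
    exact = {
        "mid_to_mid_kb": mid,
        "array1_to_obstacle_kb": a1_obs,
        "obstacle_to_array2_kb": obs_a2,
    }
    return LocusGeometry(
        mid_to_mid_kb=_display_kb(mid),
        array1_to_obstacle_kb=None if a1_obs is None else _display_kb(a1_obs),
        obstacle_to_array2_kb=None if obs_a2 is None else _display_kb(obs_a2),
        exact=exact,
    )


def nominal_layout(*, obstacle: bool = False, obstacle_strand: str = "lagging") -> LocusLayout:
    """The nominal reporter geometry: 10 kb arrays, inner edges 20 kb apart.

    Mid-to-mid distance is exactly 30 kb.  With ``obstacle=True`` a G4 insert
    is placed 11.6 kb after array 1 (8.4 kb before array 2), mirroring the
    chromosome IV obstacle's position relative to the distal array.
    """
    return LocusLayout(
        array1_pos=332_960,
        array2_pos=352_960,
        array_len_kb=10.0,
        origin_pos=320_960,
        obstacle_pos=344_560 if obstacle else None,
        obstacle_strand=obstacle_strand,
    )


def chr4_layout(
    *, array_len_kb: float = 10.0, obstacle: bool = True, obstacle_strand: str = "lagging"
) -> LocusLayout:
    """The printed chromosome IV coordinates of the engineered strains.

    lacO inserted at chrIV:332,960, tetO at chrIV:352,560 and the G4 motif at
    chrIV:344,119 (8.4 kb before the tetO array).  With ``array_len_kb=11.0``
    the mid-to-mid distance is the 30.6 kb variant.
    """
    return LocusLayout(
        array1_pos=332_960,
        array2_pos=352_560,
        array_len_kb=array_len_kb,
        origin_pos=320_960,
        obstacle_pos=344_119 if obstacle else None,
        obstacle_strand=obstacle_strand,
    )


#: Distance (kb) whose replication time the inter-array delay reports, under
#: the nominal 20 kb spacing + 10 kb array convention.
DEFAULT_DISTANCE_KB = 30.0
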