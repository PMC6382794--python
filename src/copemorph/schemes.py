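"""Landmark schemes: digitization templates for 2D landmark configurations.

A scheme describes one rigid structure as it is digitized: how many landmarks,
which of them slide along curves (semilandmarks), what kind of bilateral
symmetry the structure has, and an adjacency graph over landmarks used by
contiguity-constrained modularity tests.

Two symmetry modes are distinguished:

* ``object`` symmetry — the structure itself is bilaterally symmetric about a
  midline (e.g. a genital somite viewed dorsally).  Landmarks off the midline
  come in left/right pairs; the analysis includes a reflected-and-relabeled
  copy of every configuration.
* ``matching`` symmetry — the structure exists as separate left and right
  copies (e.g. legs); each side is digitized on its own and one side is
  reflected before superimposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx

__all__ = ["LandmarkScheme", "study_schemes"]

_SYMMETRY_MODES = ("none", "object", "matching")


@dataclass(frozen=True)
class LandmarkScheme:
    """A named digitization template.

    Parameters
    ----------
    name:
        Identifier of the structure (e.g. ``"P4Exp3"``).
    k:
        Number of landmarks, at least 3.
    slider_curves:
        Zero or more curves of sliding semilandmarks.  Each curve is an
        ordered landmark-index list whose first and last entries are fixed
        anchors; the interior entries slide along the curve tangent.
    symmetry:
        ``"none"``, ``"object"`` or ``"matching"``.
    pairing:
        For object symmetry, the left/right landmark index pairs.  For
        matching symmetry usually empty (the same label applies on either
        side).
    midline:
        Indices lying on the symmetry axis (object symmetry only).
    adjacency:
        Undirected edge list over landmark indices; must form a connected
        graph when provided.  Used for contiguous-partition modularity tests.

    Indices are 0-based internally; reports and TPS files render landmarks
    1-based, which is the numbering convention of digitizing software.
    """

    name: str
    k: int
    slider_curves: tuple[tuple[int, ...], ...] = ()
    symmetry: str = "none"
    pairing: tuple[tuple[int, int], ...] = ()
    midline: tuple[int, ...] = ()
    adjacency: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ValueError(f"scheme {self.name!r}: need at least 3 landmarks, got {self.k}")
        if self.symmetry not in _SYMMETRY_MODES:
            raise ValueError(f"scheme {self.name!r}: unknown symmetry mode {self.symmetry!r}")
        object.__setattr__(self, "slider_curves", tuple(tuple(c) for c in self.slider_curves))
        object.__setattr__(self, "pairing", tuple(tuple(p) for p in self.pairing))
        object.__setattr__(self, "midline", tuple(self.midline))
        object.__setattr__(self, "adjacency", tuple(tuple(sorted(e)) for e in self.adjacency))
        for curve in self.slider_curves:
            if len(curve) < 3:
                raise ValueError(f"scheme {self.name!r}: a slider curve needs two anchors "
                                 f"and at least one interior slider, got {curve}")
            if any(i < 0 or i >= self.k for i in curve):
                raise ValueError(f"scheme {self.name!r}: slider curve index out of range")
        sliders = self.sliders
        if len(set(sliders)) != len(sliders):
            raise ValueError(f"scheme {self.name!r}: duplicate slider index")
        if self.symmetry == "object":
            seen: set[int] = set(self.midline)
            if len(seen) != len(self.midline):
                raise ValueError(f"scheme {self.name!r}: duplicate midline index")
            for a, b in self.pairing:
                if a == b or a in seen or b in seen:
                    raise ValueError(f"scheme {self.name!r}: landmark reused in pairing/midline")
                seen.update((a, b))
            if seen != set(range(self.k)):
                missing = sorted(set(range(self.k)) - seen)
                raise ValueError(f"scheme {self.name!r}: object symmetry requires every landmark "
                                 f"paired or on the midline; unpaired: {missing}")
        if self.adjacency:
            g = self.graph()
            if g.number_of_nodes() != self.k or not nx.is_connected(g):
                raise ValueError(f"scheme {self.name!r}: adjacency graph must span all "
                                 "landmarks and be connected")

    @property
    def sliders(self) -> tuple[int, ...]:
        """Ordered indices of sliding semilandmarks (curve interiors)."""
        out: list[int] = []
        for curve in self.slider_curves:
            out.extend(curve[1:-1])
        return tuple(out)

    @property
    def tangent_dim(self) -> int:
        """Dimension of the shape tangent space: 2k - 4 for planar landmarks."""
        return 2 * self.k - 4

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.k))
        g.add_edges_from(self.adjacency)
        return g

    def reflection_relabeling(self) -> list[int]:
        """Permutation sending each landmark to its mirror partner.

        Midline landmarks map to themselves; for matching symmetry (no
        pairing) the identity is returned.
        """
        perm = list(range(self.k))
        for a, b in self.pairing:
            perm[a], perm[b] = b, a
        return perm


def _outline_cycle(k: int) -> tuple[tuple[int, int], ...]:
    return tuple((i, (i + 1) % k) for i in range(k))


def study_schemes() -> dict[str, LandmarkScheme]:
    """The five digitization schemes of the copepod study design.

    Landmark counts are Gs:45, Cr:7, P4Exp3:10, P4Enp3:7, P4CxBp:15
    (84 landmarks in total).  The genital somite (Gs) has object symmetry
    with a median pore on the midline, nine bilateral landmark pairs and 26
    equally spaced sliding semilandmarks on the two lateral edges; the paired
    appendage structures use matching (left/right) symmetry.
    """
    # Gs, 1-based layout: corners 1,2,9,10,11,18; leg-6 setae 3,12; paired
    # dorsal sensilla 4-8 vs 13-17; median pore 19; sliders 20-32 (left edge,
    # anchored at corners 2 and 9) and 33-45 (right edge, corners 11 and 18).
    gs_pairing = [(0, 9), (1, 10), (8, 17), (2, 11)]
    gs_pairing += [(3 + i, 12 + i) for i in range(5)]          # sensilla 4-8 <-> 13-17
    gs_pairing += [(19 + i, 32 + i) for i in range(13)]        # sliders 20-32 <-> 33-45
    gs_left_curve = (1, *range(19, 32), 8)                     # LM2, 20..32, LM9
    gs_right_curve = (10, *range(32, 45), 17)                  # LM11, 33..45, LM18
    gs_edges = set()
    for curve in (gs_left_curve, gs_right_curve):
        gs_edges.update(zip(curve[:-1], curve[1:]))
    # close the outline through the corners and hang interior organs off it
    gs_edges.update([(0, 1), (0, 9), (9, 10), (8, 17)])
    gs_edges.update([(0, 2), (9, 11), (18, 0)])                # setae near anterior corners, pore
    gs_edges.update([(2, 3), (3, 4), (4, 5), (5, 6), (6, 7), (7, 8)])    # left sensilla chain
    gs_edges.update([(11, 12), (12, 13), (13, 14), (14, 15), (15, 16), (16, 17)])
    gs = LandmarkScheme(
        name="Gs", k=45,
        slider_curves=(gs_left_curve, gs_right_curve),
        symmetry="object",
        pairing=tuple(gs_pairing),
        midline=(18,),
        adjacency=tuple(gs_edges),
    )
    cr = LandmarkScheme(name="Cr", k=7, symmetry="matching",
                        adjacency=_outline_cycle(7))
    p4exp3 = LandmarkScheme(name="P4Exp3", k=10, symmetry="matching",
                            adjacency=_outline_cycle(10))
    p4enp3 = LandmarkScheme(name="P4Enp3", k=7, symmetry="matching",
                            adjacency=_outline_cycle(7))
    # P4CxBp: corners 1-9 on the outline; ornamentation = spinule-row bases
    # 10,11,13,14 and pores 12,15 attached to the nearest corners.
    p4cxbp_edges = list(_outline_cycle(9))
    p4cxbp_edges += [(0, 9), (9, 10), (10, 11), (2, 11), (3, 12), (12, 13), (13, 14), (5, 14)]
    p4cxbp = LandmarkScheme(name="P4CxBp", k=15, symmetry="matching",
                            adjacency=tuple(p4cxbp_edges))
    return {s.name: s for s in (gs, cr, p4exp3, p4enp3, p4cxbp)}
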