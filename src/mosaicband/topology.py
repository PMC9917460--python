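"""Contact topology of clones on a hexagonal lattice.

A single aberrant cell in a wild-type epithelium touches different-fate
neighbours on all six of its surfaces, while each of its wild-type
neighbours commits only one surface to the contact.  As a clone grows the
number of heterotypic contacts per clonal interface cell falls toward a
constant (between 2 and 3 for compact clones), whereas wild-type interface
cells stay at one or two contacts each.  If interface signalling (JNK)
scales with the number of heterotypic contacts, this asymmetry predicts
strong signalling and apoptosis in single cells and small clones, weak
signalling in large clones and fate compartments — the clone-size scaling
this package's measurement side quantifies in images.

Cells are axial hex coordinates ``(q, r)`` with the six unit neighbours of
a pointy-top lattice; coordination number 6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

AXIAL_DIRECTIONS: tuple[tuple[int, int], ...] = (
    (1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1),
)

GROWTH_MODES = ("compact_spiral", "eden_random")


def hex_neighbors(cell: tuple[int, int]) -> list[tuple[int, int]]:
    q, r = cell
    return [(q + dq, r + dr) for dq, dr in AXIAL_DIRECTIONS]


@dataclass(frozen=True)
class HexClone:
    """A connected set of lattice cells of the aberrant genotype."""

    cells: frozenset[tuple[int, int]]
    growth_mode: str = "compact_spiral"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.cells:
            raise ValueError("clone must be non-empty")
        if not self._connected():
            raise ValueError("clone cells must be 6-neighbour connected")

    def _connected(self) -> bool:
        cells = set(self.cells)
        start = next(iter(cells))
        seen = {start}
        stack = [start]
        while stack:
            for nb in hex_neighbors(stack.pop()):
                if nb in cells and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == len(cells)

    @property
    def n(self) -> int:
        return len(self.cells)


def _spiral_order(n: int) -> list[tuple[int, int]]:
    """First n cells of the deterministic ring spiral around the origin."""
    cells = [(0, 0)]
    ring = 1
    while len(cells) < n:
        q, r = ring * AXIAL_DIRECTIONS[4][0], ring * AXIAL_DIRECTIONS[4][1]
        for side in range(6):
            dq, dr = AXIAL_DIRECTIONS[side]
            for _ in range(ring):
                cells.append((q, r))
                q, r = q + dq, r + dr
                if len(cells) > n:
                    break
        ring += 1
    return cells[:n]


def grow_clone(n: int, mode: str = "compact_spiral",
               seed: int | None = None) -> HexClone:
    """Grow a connected clone of exactly ``n`` cells.

    ``compact_spiral`` fills concentric rings around the origin
    (deterministic, roughly isotropic — the idealized compact clone).
    ``eden_random`` starts from the origin and repeatedly adds a uniformly
    random outside neighbour of the current clone (seeded), producing the
    ragged outlines real clones show.
    """
    if n < 1:
        raise ValueError("clone must have at least one cell")
    if mode not in GROWTH_MODES:
        raise ValueError(f"mode must be one of {GROWTH_MODES}")
    if mode == "compact_spiral":
        return HexClone(frozenset(_spiral_order(n)), mode, seed)
    rng = np.random.default_rng(seed)
    cells = {(0, 0)}
    frontier = set(hex_neighbors((0, 0)))
    while len(cells) < n:
        ordered = sorted(frontier)
        pick = ordered[rng.integers(len(ordered))]
        cells.add(pick)
        frontier.discard(pick)
        frontier.update(nb for nb in hex_neighbors(pick) if nb not in cells)
    return HexClone(frozenset(cells), mode, seed)


@dataclass
class ContactProfile:
    """Heterotypic contact counts of one clone's two interface populations.

    ``clone_contacts`` maps each clone cell to its number of outside
    neighbours (0 for interior cells); ``wt_contacts`` maps each outside
    cell adjacent to the clone to its number of inside neighbours.
    """

    clone_size: int
    clone_contacts: dict[tuple[int, int], int]
    wt_contacts: dict[tuple[int, int], int]

    @property
    def clone_interface_counts(self) -> np.ndarray:
        return np.array([c for c in self.clone_contacts.values() if c > 0])

    @property
    def wt_interface_counts(self) -> np.ndarray:
        return np.array(list(self.wt_contacts.values()))

    @property
    def n_interior(self) -> int:
        return sum(1 for c in self.clone_contacts.values() if c == 0)

    @property
    def total_clone_side(self) -> int:
        return int(sum(self.clone_contacts.values()))

    @property
    def total_wt_side(self) -> int:
        return int(sum(self.wt_contacts.values()))

    @property
    def mean_clone_interface(self) -> float:
        counts = self.clone_interface_counts
        return float(counts.mean()) if counts.size else 0.0

    @property
    def mean_wt_interface(self) -> float:
        counts = self.wt_interface_counts
        return float(counts.mean()) if counts.size else 0.0


def contact_profile(clone: HexClone) -> ContactProfile:
    """Count heterotypic contacts on both sides of the clone interface.

    Each shared edge contributes one contact to the clone-side cell and one
    to the wild-type-side cell, so the two totals are equal by construction.
    """
    cells = clone.cells
    clone_contacts: dict[tuple[int, int], int] = {}
    wt_contacts: dict[tuple[int, int], int] = {}
    for cell in cells:
        outside = [nb for nb in hex_neighbors(cell) if nb not in cells]
        clone_contacts[cell] = len(outside)
        for nb in outside:
            wt_contacts[nb] = wt_contacts.get(nb, 0) + 1
    return ContactProfile(clone.n, clone_contacts, wt_contacts)


def predicted_activation(
    profile: ContactProfile,
    base: float = 0.0,
    per_contact: float = 1.0,
    saturating: bool = False,
    sat_scale: float = 1.0,
    sat_rate: float = 0.5,
) -> dict[str, float]:
    """Population-mean predicted signal under the contact-proportional model.

    ``signal(cell) = base + per_contact * contacts`` (linear default), or a
    saturating variant ``base + sat_scale * (1 - exp(-sat_rate*contacts))``.
    Returns means for clone interface cells, wild-type interface cells and
    clone interior cells, plus the whole-clone mean.
    """
    if per_contact < 0:
        raise ValueError("per_contact must be >= 0")

    def signal(contacts: np.ndarray) -> np.ndarray:
        contacts = np.asarray(contacts, dtype=float)
        if saturating:
            return base + sat_scale * (1.0 - np.exp(-sat_rate * contacts))
        return base + per_contact * contacts

    clone_iface = profile.clone_interface_counts
    wt_iface = profile.wt_interface_counts
    all_clone = np.array(list(profile.clone_contacts.values()), dtype=float)
    return {
        "clone_interface": float(signal(clone_iface).mean()) if clone_iface.size
        else np.nan,
        "wt_interface": float(signal(wt_iface).mean()) if wt_iface.size
        else np.nan,
        "interior": float(base) if profile.n_interior else np.nan,
        "whole_clone": float(signal(all_clone).mean()),
    }


def scaling_curve(
    sizes: list[int],
    mode: str = "compact_spiral",
    base: float = 0.0,
    per_contact: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean contacts and predicted signal per population across clone sizes.

    The tabular form of the model's central prediction: clone-interface
    signal falls steeply with size while wild-type-interface signal stays
    low with a small dynamic range.
    """
    rows = []
    for n in sizes:
        clone = grow_clone(n, mode, seed)
        prof = contact_profile(clone)
        act = predicted_activation(prof, base, per_contact)
        for pop, contacts in (
            ("clone_interface", prof.mean_clone_interface),
            ("wt_interface", prof.mean_wt_interface),
            ("whole_clone", prof.total_clone_side / prof.clone_size),
        ):
            rows.append({"n": n, "population": pop, "mean_contacts": contacts,
                         "mean_signal": act[pop]})
    return pd.DataFrame(rows)
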