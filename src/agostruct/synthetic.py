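"""Synthetic fixtures with exact ground truth for every pipeline stage.

Each generator returns its fixture together with a ground-truth dictionary
(the sidecar), so tests recover expected values from the generator rather
than re-deriving them ad hoc.  All generators are seed-deterministic:
identical arguments and seed give identical output.  Fixtures are small
(≤ 500 atoms, ≤ 2000 particles) by design.
"""

from __future__ import annotations

import math

import numpy as np

from .assembly import CATEGORIES, make_assembly_graph
from .humanization import IMGT_CDR_SPANS, GermlineRecord
from .kinetics import KineticParams, Sensorgram, simulate_series
from .structmodel import Atom, SequenceRecord, Structure

__all__ = [
    "two_sphere_union_areas",
    "make_sphere_pair",
    "make_slab_complex",
    "make_beta_ladder",
    "make_fv_pair",
    "make_sensorgram_set",
    "make_assembly_set",
    "SPR_LADDER_NM",
]

# The SPR analyte concentration ladder used throughout (nM).
SPR_LADDER_NM = (0.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Two-sphere SASA oracle

def two_sphere_union_areas(r1: float, r2: float, separation: float,
                           probe: float = 1.4) -> tuple[float, float]:
    """Exact exposed areas of two solvent-expanded spheres (spherical caps).

    Returns the per-sphere exposed areas of the union surface; the total is
    their sum.  Coincident equal spheres count as one sphere, attributed to
    the first.
    """
    if r1 <= 0 or r2 <= 0:
        raise ValueError("radii must be positive")
    if separation < 0:
        raise ValueError("negative separation")
    big_r1, big_r2 = r1 + probe, r2 + probe
    d = separation
    if d >= big_r1 + big_r2:
        return 4 * math.pi * big_r1 ** 2, 4 * math.pi * big_r2 ** 2
    if d <= abs(big_r1 - big_r2):
        # one sphere engulfs the other (or exact coincidence: first wins)
        if big_r1 >= big_r2:
            return 4 * math.pi * big_r1 ** 2, 0.0
        return 0.0, 4 * math.pi * big_r2 ** 2
    x1 = (d * d + big_r1 ** 2 - big_r2 ** 2) / (2 * d)
    x2 = d - x1
    area1 = 2 * math.pi * big_r1 * (big_r1 + x1)
    area2 = 2 * math.pi * big_r2 * (big_r2 + x2)
    return area1, area2


def make_sphere_pair(r1: float, r2: float, separation: float,
                     probe: float = 1.4) -> tuple[Structure, dict]:
    """Two-atom structure with analytically known SASA.

    The atoms use elements C and N so a custom radii set can give them the
    requested van der Waals radii; the ground truth carries that radii set.
    """
    a1, a2 = two_sphere_union_areas(r1, r2, separation, probe)
    structure = Structure([
        Atom("A", 1, "", "SPH", "C1", "C", (0.0, 0.0, 0.0)),
        Atom("B", 1, "", "SPH", "N1", "N", (separation, 0.0, 0.0)),
    ])
    truth = {
        "radii_set": {"C": r1, "N": r2},
        "probe_radius": probe,
        "per_atom_area": [a1, a2],
        "total": a1 + a2,
    }
    return structure, truth


# ---------------------------------------------------------------------------
# Slab complex with a designed interface decomposition

def make_slab_complex(contact_split: tuple[float, ...],
                      n_contacts: int = 100) -> tuple[Structure, dict]:
    """Multi-chain fixture whose per-chain interface split is exact.

    Chain ``B`` carries ``n_contacts`` isolated contact sites, each an atom
    pair buried against one atom of an A-side chain; sites are 12 Å apart so
    every site is an independent identical two-atom interface.  A-side part
    *i* owns a count of sites proportional to ``contact_split[i]``
    (largest-remainder apportionment), so the BSA fractions equal the count
    ratios exactly by symmetry.
    """
    if abs(sum(contact_split) - 1.0) > 1e-9:
        raise ValueError("contact fractions must sum to 1")
    if any(f < 0 for f in contact_split):
        raise ValueError("negative contact fraction")
    counts = _largest_remainder([f * n_contacts for f in contact_split], n_contacts)
    if sum(1 for c in counts if c > 0) == 0:
        raise ValueError("infeasible split: no contacts at all")

    atoms: list[Atom] = []
    site = 0
    part_chains = []
    for part_idx, count in enumerate(counts):
        chain = chr(ord("C") + part_idx)  # parts: C, D, E, ...
        part_chains.append(chain)
        for k in range(count):
            x = 12.0 * site
            atoms.append(Atom(chain, site + 1, "", "GLY", "CA", "C", (x, 4.0, 0.0)))
            site += 1
    for s in range(n_contacts):
        atoms.append(Atom("B", s + 1, "", "GLY", "CA", "C", (12.0 * s, 0.0, 0.0)))

    truth = {
        "part_chains": part_chains,
        "side_b_chain": "B",
        "counts": counts,
        "fractions": [c / n_contacts for c in counts],
    }
    return Structure(atoms), truth


def _largest_remainder(raw: list[float], total: int) -> list[int]:
    floors = [int(math.floor(v)) for v in raw]
    deficit = total - sum(floors)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - floors[i]), i))
    for i in order[:deficit]:
        floors[i] += 1
    return floors


# ---------------------------------------------------------------------------
# Antiparallel beta ladder with known mainchain hydrogen bonds

def make_beta_ladder(n_residues: int, registry: str = "antiparallel",
                     ) -> tuple[Structure, dict]:
    """Ideal antiparallel two-strand sheet with a known H-bond ladder.

    Even-indexed residues of strand A point their backbone N and O toward
    the partner strand (N···O ≈ 2.9 Å); odd-indexed residues point away.
    The ground truth lists every intended mainchain hydrogen bond as
    ``(residue_a, atom_a, residue_b, atom_b)``.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues per strand")
    if registry != "antiparallel":
        raise ValueError(f"unsupported registry {registry!r}")

    spacing, gap = 3.4, 4.8
    reach = 0.95  # how far bonded N/O lean toward the partner strand
    atoms: list[Atom] = []
    hbonds: list[tuple] = []

    def backbone(chain: str, resnum: int, x: float, y_ca: float, y_no: float):
        atoms.append(Atom(chain, resnum, "", "ALA", "N", "N", (x - 0.6, y_no, 0.0)))
        atoms.append(Atom(chain, resnum, "", "ALA", "CA", "C", (x, y_ca, 0.0)))
        atoms.append(Atom(chain, resnum, "", "ALA", "C", "C", (x + 0.9, y_ca, 0.4)))
        atoms.append(Atom(chain, resnum, "", "ALA", "O", "O", (x + 0.6, y_no, 0.0)))
        atoms.append(Atom(chain, resnum, "", "ALA", "CB", "C",
                          (x, y_ca, 1.5 if chain == "A" else -1.5)))

    for i in range(n_residues):
        x = spacing * i
        bonded = i % 2 == 0
        res_a = i + 1
        res_b = 100 + (n_residues - i)  # strand B numbered antiparallel
        backbone("A", res_a, x, 0.0, reach if bonded else -reach)
        backbone("B", res_b, x, gap, gap - reach if bonded else gap + reach)
        if bonded:
            hbonds.append((("A", res_a, ""), "N", ("B", res_b, ""), "O"))
            hbonds.append((("A", res_a, ""), "O", ("B", res_b, ""), "N"))

    return Structure(atoms), {"hbonds": hbonds}


# ---------------------------------------------------------------------------
# Fv / germline pairs with exact identity

def make_fv_pair(identity_target: float, cdr_marks: bool = False,
                 seed: int = 0, n_positions: int = 100,
                 chain_type: str = "heavy") -> tuple[SequenceRecord, GermlineRecord, dict]:
    """A parent Fv sequence and donor germline with exact percent identity.

    The germline occupies ``n_positions`` of a 104-column IMGT-style V frame
    (frame gaps sit inside CDR1/CDR2).  The parent differs from the germline
    at exactly ``round((1 - identity/100) * n_positions)`` positions.  With
    ``cdr_marks`` the mutated positions are drawn from CDR columns first, so
    grafting bookkeeping can track them.
    """
    if not 0 <= identity_target <= 100:
        raise ValueError("identity_target must be a percentage")
    n_mut_exact = (100.0 - identity_target) / 100.0 * n_positions
    n_mut = round(n_mut_exact)
    if abs(n_mut - n_mut_exact) > 1e-9:
        raise ValueError(
            f"identity {identity_target}% is not achievable at {n_positions} positions")

    rng = np.random.default_rng(seed)
    frame_cols = 104
    n_gaps = frame_cols - n_positions
    if n_gaps < 0:
        raise ValueError("n_positions exceeds the 104-column V frame")
    # Place frame gaps inside CDR1 then CDR2 (where real germlines carry them).
    gap_pool = list(range(30, 39)) + list(range(58, 66))
    gap_cols = set(gap_pool[:n_gaps])

    gapped = []
    for col in range(1, frame_cols + 1):
        gapped.append("." if col in gap_cols else AA20[rng.integers(len(AA20))])
    germline = GermlineRecord(f"SYNV-{seed}*01", "synthetic", "".join(gapped))

    occupied = [c for c in range(1, frame_cols + 1) if c not in gap_cols]
    cdr_cols = [c for c in occupied
                if any(lo <= c <= hi for lo, hi in IMGT_CDR_SPANS.values())]
    fr_cols = [c for c in occupied if c not in cdr_cols]
    # Scatter the mutated columns (a contiguous mismatch block would let the
    # numbering aligner trade mismatches for gaps and break the exact count).
    if cdr_marks:
        pool = list(rng.permutation(cdr_cols)) + list(rng.permutation(fr_cols))
    else:
        pool = list(rng.permutation(fr_cols)) + list(rng.permutation(cdr_cols))
    mutate = set(int(c) for c in pool[:n_mut])

    parent_letters = []
    for col in occupied:
        aa = germline.gapped_sequence[col - 1]
        if col in mutate:
            choices = AA20.replace(aa, "")
            aa = choices[rng.integers(len(choices))]
        parent_letters.append(aa)
    parent = SequenceRecord(
        id=f"parent-{seed}",
        residues="".join(parent_letters),
        numbering=tuple((i + 1, "") for i in range(n_positions)),
    )
    truth = {
        "identity_pct": 100.0 * (n_positions - n_mut) / n_positions,
        "n_mutations": n_mut,
        "mutated_imgt_columns": sorted(mutate),
        "cdr_columns": cdr_cols,
        "chain_type": chain_type,
    }
    return parent, germline, truth


# ---------------------------------------------------------------------------
# Sensorgram sets

def make_sensorgram_set(params: KineticParams = KineticParams(1.4e5, 6.0e-4, 100.0),
                        concs_nm: tuple[float, ...] = SPR_LADDER_NM,
                        t_assoc: float = 300.0, t_dissoc: float = 300.0,
                        noise_sd: float = 0.0, seed: int = 0,
                        ) -> tuple[list[Sensorgram], dict]:
    """A concentration-ladder sensorgram series with known parameters."""
    concs = [c * 1e-9 for c in concs_nm]
    series = simulate_series(params, concs, t_assoc, t_dissoc,
                             noise_sd=noise_sd, seed=seed)
    truth = {"kon": params.kon, "koff": params.koff, "rmax": params.rmax,
             "kd": params.kd, "noise_sd": noise_sd}
    return series, truth


# ---------------------------------------------------------------------------
# Assembly particle sets

def make_assembly_set(proportions: dict[str, float], n: int,
                      seed: int = 0) -> tuple[list, dict]:
    """``n`` assembly graphs with exact per-category counts.

    Counts are ``n * proportion`` with largest-remainder correction so they
    sum to ``n``.  Linear particles are open hub–dimer chains of 2–4 hubs;
    ring particles carry the hub count their category dictates
    (lt_tetragonal: 3, >hexagonal: 7–9).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    unknown = set(proportions) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories {sorted(unknown)}")
    if abs(sum(proportions.values()) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")

    rng = np.random.default_rng(seed)
    cats = [c for c in CATEGORIES if proportions.get(c, 0) > 0]
    counts = _largest_remainder([proportions[c] * n for c in cats], n)
    ring_hubs = {"lt_tetragonal": 3, "tetragonal": 4, "pentagonal": 5,
                 "hexagonal": 6}

    graphs, labels = [], []
    uid = 0
    for cat, count in zip(cats, counts):
        for _ in range(count):
            if cat == "linear":
                k = int(rng.integers(2, 5))
                edges = []
                for h in range(k - 1):
                    edges.append((f"H{uid}_{h}", f"D{uid}_{h}"))
                    edges.append((f"H{uid}_{h + 1}", f"D{uid}_{h}"))
            else:
                k = ring_hubs.get(cat, int(rng.integers(7, 10)))
                edges = []
                for h in range(k):
                    edges.append((f"H{uid}_{h}", f"D{uid}_{h}"))
                    edges.append((f"H{uid}_{(h + 1) % k}", f"D{uid}_{h}"))
            graphs.append(make_assembly_graph(edges))
            labels.append(cat)
            uid += 1

    order = rng.permutation(len(graphs))
    graphs = [graphs[i] for i in order]
    labels = [labels[i] for i in order]
    truth = {"labels": labels,
             "counts": {c: labels.count(c) for c in CATEGORIES}}
    return graphs, truth
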