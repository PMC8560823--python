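"""Buried-surface and contact analysis of protein–protein interfaces.

The quantitative core of the toolkit: solvent-accessible surface area (SASA)
by Shrake–Rupley sphere sampling, buried surface area (BSA) of a binary
interface, per-part decomposition (e.g. heavy-chain vs light-chain paratope
contributions), interface-residue identification by ΔSASA, typed residue
contact classification (ionic / hydrogen bond / hydrophobic, with
mainchain–mainchain hydrogen bonds flagged), and assignment of epitope
residues to the packaged A/B/C interface regions of the Tie2 Fn3 epitope.

Definitions
-----------
SASA is the area traced by the centre of a probe sphere (default 1.4 Å)
rolled over the van der Waals spheres of the heavy atoms.  BSA of two sides
A and B is ``(SASA_A + SASA_B - SASA_AB) / 2``.  Hydrogens, when present,
are ignored (united-atom convention).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structmodel import Atom, SelectionSpec, Structure, select

__all__ = [
    "SasaParams",
    "SasaResult",
    "Contact",
    "InterfaceReport",
    "compute_sasa",
    "buried_surface_area",
    "bsa_decompose",
    "interface_residues",
    "classify_contacts",
    "assign_regions",
    "analyze_interface",
    "TIE2_EPITOPE_REGIONS",
]

# Bondi-type van der Waals radii (Å) for the common protein elements.
DEFAULT_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "H": 1.20, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
FALLBACK_RADIUS = 1.70


@dataclass(frozen=True)
class SasaParams:
    probe_radius: float = 1.4
    points_per_atom: int = 960
    radii_set: dict | None = None
    ignore_hydrogens: bool = True

    def __post_init__(self):
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be > 0")
        if self.points_per_atom < 100:
            raise ValueError("points_per_atom must be >= 100")

    def radius_of(self, element: str) -> float:
        radii = self.radii_set if self.radii_set is not None else DEFAULT_RADII
        if element not in radii:
            warnings.warn(f"no vdW radius for element {element!r}; using fallback "
                          f"{FALLBACK_RADIUS} Å", stacklevel=3)
            return FALLBACK_RADIUS
        return radii[element]


@dataclass
class SasaResult:
    per_atom_area: dict[int, float]          # atom index -> Å²
    per_residue_area: dict[tuple, float]     # residue id -> Å²
    total: float


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (Fibonacci lattice)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    theta = phi * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def compute_sasa(structure: Structure, params: SasaParams = SasaParams()) -> SasaResult:
    """Shrake–Rupley SASA: per-atom, per-residue and total areas in Å².

    Deterministic for a fixed point count.  A surface point of atom *i* is
    occluded by atom *j* when it lies strictly inside *j*'s solvent-expanded
    sphere; a point lying exactly on that sphere (coincident duplicate atoms)
    is ceded to the lower-indexed atom, so exact duplicates contribute the
    area of a single sphere in total.
    """
    atoms = [a for a in structure.atoms
             if not (params.ignore_hydrogens and a.element == "H")]
    if not atoms:
        raise ValueError("cannot compute SASA of an empty structure")

    coords = np.array([a.position for a in atoms])
    radii = np.array([params.radius_of(a.element) for a in atoms]) + params.probe_radius
    unit = _sphere_points(params.points_per_atom)
    tree = cKDTree(coords)
    max_r = radii.max()

    per_atom: dict[int, float] = {}
    per_res: dict[tuple, float] = {}
    eps = 1e-9
    for i, atom in enumerate(atoms):
        ri = radii[i]
        pts = coords[i] + ri * unit
        neighbours = [j for j in tree.query_ball_point(coords[i], ri + max_r) if j != i]
        exposed = np.ones(len(pts), dtype=bool)
        for j in neighbours:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            rj2 = radii[j] ** 2
            exposed &= d2 > rj2 - eps
            if j < i:  # boundary ties go to the lower-indexed atom
                exposed &= d2 > rj2 + eps
            if not exposed.any():
                break
        area = 4.0 * math.pi * ri * ri * exposed.sum() / len(pts)
        per_atom[i] = area
        per_res[atom.residue_id] = per_res.get(atom.residue_id, 0.0) + area

    return SasaResult(per_atom, per_res, sum(per_atom.values()))


def _check_disjoint(complex_structure: Structure,
                    side_a: SelectionSpec, side_b: SelectionSpec):
    sa = select(complex_structure, side_a)
    sb = select(complex_structure, side_b)
    ids_a = {(a.residue_id, a.atom_name) for a in sa.atoms}
    ids_b = {(a.residue_id, a.atom_name) for a in sb.atoms}
    if ids_a & ids_b:
        raise ValueError("side_a and side_b selections overlap")
    return sa, sb


def buried_surface_area(complex_structure: Structure,
                        side_a: SelectionSpec, side_b: SelectionSpec,
                        params: SasaParams = SasaParams()) -> float:
    """BSA = (SASA_A + SASA_B − SASA_AB)/2 over the two selections, in Å²."""
    sa, sb = _check_disjoint(complex_structure, side_a, side_b)
    both = Structure(sa.atoms + sb.atoms)
    area_a = compute_sasa(sa, params).total
    area_b = compute_sasa(sb, params).total
    area_ab = compute_sasa(both, params).total
    return 0.5 * (area_a + area_b - area_ab)


def bsa_decompose(complex_structure: Structure,
                  side_a_parts: list[SelectionSpec], side_b: SelectionSpec,
                  params: SasaParams = SasaParams()) -> dict[int, dict]:
    """Split the A-side BSA into per-part contributions (Å² and fractions).

    ``side_a_parts`` must partition side A.  The A-side ΔSASA of each part is
    exact; the B-side ΔSASA is attributed to parts by leave-one-part-out
    occlusion and renormalised so that part areas sum exactly to the
    undivided BSA.
    """
    parts = [select(complex_structure, p) for p in side_a_parts]
    sb = select(complex_structure, side_b)
    part_ids = [{(a.residue_id, a.atom_name) for a in p.atoms} for p in parts]
    for i in range(len(part_ids)):
        for j in range(i + 1, len(part_ids)):
            if part_ids[i] & part_ids[j]:
                raise ValueError(f"side_a parts {i} and {j} overlap: not a partition")

    all_a = Structure([a for p in parts for a in p.atoms])
    union = Structure(all_a.atoms + sb.atoms)
    sasa_a_alone = compute_sasa(all_a, params)
    sasa_union = compute_sasa(union, params)
    sasa_b_alone = compute_sasa(sb, params)

    # A-side ΔSASA per part (atoms of all_a keep their order in union).
    delta_a_parts = []
    offset = 0
    for p in parts:
        d = 0.0
        for k in range(len(p.atoms)):
            d += sasa_a_alone.per_atom_area[offset + k] - sasa_union.per_atom_area[offset + k]
        delta_a_parts.append(d)
        offset += len(p.atoms)

    # B-side ΔSASA attributable to each part: occlusion of B by that part alone.
    delta_b_total = sasa_b_alone.total - sum(
        sasa_union.per_atom_area[offset + k] for k in range(len(sb.atoms))
    )
    raw_b = []
    for p in parts:
        with_part = Structure(p.atoms + sb.atoms)
        sasa_with = compute_sasa(with_part, params)
        b_present = sum(sasa_with.per_atom_area[len(p.atoms) + k]
                        for k in range(len(sb.atoms)))
        raw_b.append(sasa_b_alone.total - b_present)
    raw_sum = sum(raw_b)
    scale = delta_b_total / raw_sum if raw_sum > 0 else 0.0
    delta_b_parts = [r * scale for r in raw_b]

    areas = [0.5 * (da + db) for da, db in zip(delta_a_parts, delta_b_parts)]
    total = sum(areas)
    return {
        i: {"bsa": areas[i], "fraction": areas[i] / total if total > 0 else 0.0}
        for i in range(len(parts))
    }


def interface_residues(complex_structure: Structure,
                       side_a: SelectionSpec, side_b: SelectionSpec,
                       params: SasaParams = SasaParams(),
                       min_delta: float = 0.1) -> dict[str, list[tuple]]:
    """Residues whose SASA drops by more than ``min_delta`` Å² on complexation.

    Returns per-side lists of ``(residue_id, delta_sasa)`` sorted by ΔSASA
    descending.
    """
    sa, sb = _check_disjoint(complex_structure, side_a, side_b)
    both = Structure(sa.atoms + sb.atoms)
    res_alone: dict[tuple, float] = {}
    res_alone.update(compute_sasa(sa, params).per_residue_area)
    res_alone.update(compute_sasa(sb, params).per_residue_area)
    res_complex = compute_sasa(both, params).per_residue_area

    def side_list(side: Structure) -> list[tuple]:
        out = []
        for rid in {a.residue_id for a in side.atoms}:
            delta = res_alone.get(rid, 0.0) - res_complex.get(rid, 0.0)
            if delta > min_delta:
                out.append((rid, delta))
        out.sort(key=lambda t: (-t[1], t[0]))
        return out

    return {"side_a": side_list(sa), "side_b": side_list(sb)}


# ---------------------------------------------------------------------------
# Contact classification

@dataclass(frozen=True)
class Contact:
    residue_a: tuple[str, int, str]
    residue_b: tuple[str, int, str]
    kind: str  # hydrogen_bond | ionic | hydrophobic | mainchain_hbond
    distance: float
    atoms: tuple[str, str]


@dataclass(frozen=True)
class ContactCriteria:
    """Heavy-atom distance cutoffs for typed contacts (community defaults)."""

    hbond_cutoff: float = 3.5
    ionic_cutoff: float = 4.0
    hydrophobic_cutoff: float = 4.5


# Formal-charge-bearing sidechain heavy atoms.
POSITIVE_ATOMS = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
                  ("HIS", "ND1"), ("HIS", "NE2")}
NEGATIVE_ATOMS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}

# Hydrogen-bond donors (with implicit H) and acceptors; backbone N donates,
# backbone O accepts, for every residue type.
SIDECHAIN_DONORS = {("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("CYS", "SG"),
                    ("ASN", "ND2"), ("GLN", "NE2"), ("HIS", "ND1"), ("HIS", "NE2"),
                    ("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
                    ("TRP", "NE1")}
SIDECHAIN_ACCEPTORS = {("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
                       ("ASN", "OD1"), ("GLN", "OE1"), ("HIS", "ND1"),
                       ("HIS", "NE2"), ("ASP", "OD1"), ("ASP", "OD2"),
                       ("GLU", "OE1"), ("GLU", "OE2"), ("MET", "SD")}


def _is_donor(a: Atom) -> bool:
    return (a.atom_name == "N") or ((a.residue_name, a.atom_name) in SIDECHAIN_DONORS)


def _is_acceptor(a: Atom) -> bool:
    return (a.atom_name in ("O", "OXT")) or \
        ((a.residue_name, a.atom_name) in SIDECHAIN_ACCEPTORS)


def _is_apolar_carbon(a: Atom) -> bool:
    # Backbone carbonyl carbon is polarised; all other carbons count.
    return a.element == "C" and a.atom_name != "C"


def classify_contacts(complex_structure: Structure,
                      side_a: SelectionSpec, side_b: SelectionSpec,
                      criteria: ContactCriteria = ContactCriteria()) -> list[Contact]:
    """Typed inter-side residue–residue contacts.

    For each residue pair the first matching rule in precedence order
    ionic > hydrogen bond > hydrophobic types the contact, reporting the
    closest qualifying atom pair.  A hydrogen bond whose atoms are both
    mainchain N/O is flagged ``mainchain_hbond``.
    """
    sa, sb = _check_disjoint(complex_structure, side_a, side_b)
    if not sa.atoms or not sb.atoms:
        return []
    coords_b = np.array([a.position for a in sb.atoms])
    tree_b = cKDTree(coords_b)
    max_cut = max(criteria.hbond_cutoff, criteria.ionic_cutoff,
                  criteria.hydrophobic_cutoff)

    # residue pair -> kind -> list of (distance, atom pair)
    found: dict[tuple, dict[str, list[tuple[float, tuple[str, str]]]]] = {}
    for a in sa.atoms:
        for j in tree_b.query_ball_point(a.position, max_cut):
            b = sb.atoms[j]
            d = math.dist(a.position, b.position)
            key = (a.residue_id, b.residue_id)
            slot = found.setdefault(key, {})

            charge_pair = (
                ((a.residue_name, a.atom_name) in POSITIVE_ATOMS and
                 (b.residue_name, b.atom_name) in NEGATIVE_ATOMS) or
                ((a.residue_name, a.atom_name) in NEGATIVE_ATOMS and
                 (b.residue_name, b.atom_name) in POSITIVE_ATOMS))
            if charge_pair and d <= criteria.ionic_cutoff:
                slot.setdefault("ionic", []).append((d, (a.atom_name, b.atom_name)))
            hb = ((_is_donor(a) and _is_acceptor(b)) or
                  (_is_acceptor(a) and _is_donor(b)))
            if hb and d <= criteria.hbond_cutoff:
                mainchain = (a.atom_name in ("N", "O", "OXT") and
                             b.atom_name in ("N", "O", "OXT"))
                kind = "mainchain_hbond" if mainchain else "hydrogen_bond"
                slot.setdefault(kind, []).append((d, (a.atom_name, b.atom_name)))
            if (_is_apolar_carbon(a) and _is_apolar_carbon(b)
                    and d <= criteria.hydrophobic_cutoff):
                slot.setdefault("hydrophobic", []).append((d, (a.atom_name, b.atom_name)))

    # Precedence per residue pair: ionic > hydrogen bond > hydrophobic.  For
    # the winning hydrogen-bond kind every qualifying donor–acceptor atom
    # pair is emitted (a β-ladder shows its full rung list); for ionic and
    # hydrophobic the closest atom pair represents the residue pair.
    contacts: list[Contact] = []
    for (rid_a, rid_b), slot in sorted(found.items()):
        for kind in ("ionic", "mainchain_hbond", "hydrogen_bond", "hydrophobic"):
            if kind not in slot:
                continue
            pairs = sorted(slot[kind])
            if kind in ("mainchain_hbond", "hydrogen_bond"):
                for d, names in pairs:
                    contacts.append(Contact(rid_a, rid_b, kind, d, names))
            else:
                d, names = pairs[0]
                contacts.append(Contact(rid_a, rid_b, kind, d, names))
            break
    return contacts


# ---------------------------------------------------------------------------
# Epitope region assignment

# The three interface regions of the Tie2 Fn3 epitope for the agonistic
# antibody: A (ionic/H-bond contacts of the heavy chain with βA/βG), B (the
# central hydrophobic core around V730), C (light-chain framework contacts).
# Assignment is a set: I647 belongs to both A and B.
TIE2_EPITOPE_REGIONS: dict[int, frozenset[str]] = {
    643: frozenset("A"), 644: frozenset("A"), 645: frozenset("A"),
    646: frozenset("A"), 647: frozenset("AB"), 727: frozenset("A"),
    650: frozenset("B"), 707: frozenset("B"), 730: frozenset("B"),
    732: frozenset("B"),
    677: frozenset("C"), 705: frozenset("C"), 728: frozenset("C"),
}


@dataclass
class InterfaceReport:
    total_bsa: float
    bsa_by_partner_chain: dict[str, float]
    interface_residues: dict[str, list[tuple]]
    contacts: list[Contact] = field(default_factory=list)
    region_assignment: dict[tuple, frozenset[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "total_bsa": self.total_bsa,
            "bsa_by_partner_chain": self.bsa_by_partner_chain,
            "interface_residues": {
                side: [[list(rid), delta] for rid, delta in rows]
                for side, rows in self.interface_residues.items()
            },
            "contacts": [
                {"residue_a": list(c.residue_a), "residue_b": list(c.residue_b),
                 "kind": c.kind, "distance": c.distance, "atoms": list(c.atoms)}
                for c in self.contacts
            ],
            "region_assignment": {
                f"{rid[0]}:{rid[1]}{rid[2]}": sorted(regions)
                for rid, regions in self.region_assignment.items()
            },
        }


def assign_regions(report: InterfaceReport,
                   region_map: dict[int, frozenset[str]] | None = None) -> InterfaceReport:
    """Label each epitope (side-b) interface residue with its A/B/C region.

    Residues absent from the table stay unassigned.  With no table available
    the report is returned all-unassigned with a warning.
    """
    if region_map is None:
        region_map = TIE2_EPITOPE_REGIONS
    if not region_map:
        warnings.warn("region table missing; all residues left unassigned", stacklevel=2)
        report.region_assignment = {}
        return report
    assignment = {}
    for side in ("side_a", "side_b"):
        for rid, _delta in report.interface_residues.get(side, []):
            regions = region_map.get(rid[1])
            if regions:
                assignment[rid] = regions
    report.region_assignment = assignment
    return report


def analyze_interface(complex_structure: Structure,
                      side_a: SelectionSpec, side_b: SelectionSpec,
                      params: SasaParams = SasaParams(),
                      min_delta: float = 0.1,
                      criteria: ContactCriteria = ContactCriteria()) -> InterfaceReport:
    """Full interface report: BSA, per-chain split, residues, typed contacts."""
    total = buried_surface_area(complex_structure, side_a, side_b, params)
    sa = select(complex_structure, side_a)
    chain_specs = {c: SelectionSpec(chains=frozenset({c})) for c in sa.chains()}
    if len(chain_specs) > 1:
        decomposition = bsa_decompose(complex_structure, list(chain_specs.values()),
                                      side_b, params)
        by_chain = {c: decomposition[i]["bsa"]
                    for i, c in enumerate(chain_specs)}
    else:
        by_chain = {c: total for c in chain_specs}
    residues = interface_residues(complex_structure, side_a, side_b, params, min_delta)
    contacts = classify_contacts(complex_structure, side_a, side_b, criteria)
    return InterfaceReport(total, by_chain, residues, contacts)
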