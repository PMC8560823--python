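"""Antibody Fv humanization: IMGT numbering, germline selection, CDR
grafting, and structure-guided back-mutation flagging.

The workflow mirrors classical structure-based humanization of a murine
monoclonal: number the parental variable domain on the IMGT unique frame,
pick the human germline V gene with the highest framework identity as FR
donor, graft the parental CDRs (IMGT CDR1 27–38, CDR2 56–65, CDR3 105–117)
onto the donor frameworks, and then flag framework positions whose parental
residue makes structurally important contacts in the template complex —
with the antigen, across the VH–VL interface, or supporting a CDR — as
candidate back mutations.

Numbering is obtained by aligning the query to the best-matching IMGT-gapped
germline and inheriting that germline's position frame; insertions relative
to the frame receive letter insertion codes, numbered symmetrically from
both ends inside CDR3 per the IMGT convention.  This germline-anchored
scheme is deterministic and adequate for V regions close to the packaged
reference set; it is not a profile-HMM and will misnumber highly divergent
domains.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

from Bio import Align

from .structmodel import Atom, SequenceRecord, Structure

__all__ = [
    "IMGT_CDR_SPANS",
    "NumberedFv",
    "GermlineRecord",
    "GraftResult",
    "BackMutation",
    "BackMutationThresholds",
    "imgt_number",
    "germline_identity",
    "select_germline",
    "graft_cdrs",
    "flag_back_mutations",
    "build_variant",
]

# IMGT unique-numbering CDR intervals (inclusive).
IMGT_CDR_SPANS = {"CDR1": (27, 38), "CDR2": (56, 65), "CDR3": (105, 117)}

Position = tuple[int, str]  # (IMGT position, insertion code)


def cdr_of(position: Position) -> str | None:
    num = position[0]
    for name, (lo, hi) in IMGT_CDR_SPANS.items():
        if lo <= num <= hi:
            return name
    return None


@dataclass(frozen=True)
class GermlineRecord:
    """An IMGT-gapped germline V-gene sequence (``.`` or ``-`` marks gaps)."""

    gene_name: str
    species: str
    gapped_sequence: str

    @property
    def positions(self) -> tuple[Position, ...]:
        return tuple((i + 1, "") for i, c in enumerate(self.gapped_sequence)
                     if c not in ".-")

    @property
    def ungapped(self) -> str:
        return "".join(c for c in self.gapped_sequence if c not in ".-")

    def residue_at(self, position: Position) -> str | None:
        num, icode = position
        if icode or num > len(self.gapped_sequence):
            return None
        c = self.gapped_sequence[num - 1]
        return None if c in ".-" else c


@dataclass
class NumberedFv:
    """A variable-domain sequence with IMGT position labels and span sets."""

    chain_type: str  # heavy | light
    sequence: str
    imgt_positions: tuple[Position, ...]

    def __post_init__(self):
        if self.chain_type not in {"heavy", "light"}:
            raise ValueError("chain_type must be 'heavy' or 'light'")
        if len(self.sequence) != len(self.imgt_positions):
            raise ValueError("every sequence letter needs exactly one position label")
        if len(set(self.imgt_positions)) != len(self.imgt_positions):
            raise ValueError("duplicate IMGT position labels")

    def residue_at(self, position: Position) -> str | None:
        try:
            return self.sequence[self.imgt_positions.index(position)]
        except ValueError:
            return None

    def fr_positions(self) -> list[Position]:
        return [p for p in self.imgt_positions if cdr_of(p) is None]

    def cdr_positions(self) -> list[Position]:
        return [p for p in self.imgt_positions if cdr_of(p) is not None]

    def cdr_sequence(self, name: str) -> str:
        lo, hi = IMGT_CDR_SPANS[name]
        return "".join(c for c, p in zip(self.sequence, self.imgt_positions)
                       if lo <= p[0] <= hi)


def _local_frame_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    # The query's CDR3/FR4 tail extends past the germline V region: don't
    # penalise end gaps in the germline.
    aligner.open_right_insertion_score = 0.0
    aligner.extend_right_insertion_score = 0.0
    return aligner


def _symmetric_cdr3_positions(count: int) -> list[Position]:
    """IMGT positions for a CDR3 of ``count`` residues (symmetric numbering).

    Lengths up to 13 use a contiguous-from-both-ends subset of 105–117;
    longer loops place lettered insertions on position 111 (rising codes
    from the N-terminal side) and 112 (falling codes from the C-terminal
    side), which reproduces the IMGT gap-from-the-middle convention.
    """
    base = list(range(105, 118))
    if count <= len(base):
        n_front = (count + 1) // 2
        n_back = count - n_front
        nums = base[:n_front] + (base[-n_back:] if n_back else [])
        return [(n, "") for n in nums]
    extra = count - len(base)
    n_front_extra = (extra + 1) // 2
    n_back_extra = extra - n_front_extra
    front = [(n, "") for n in range(105, 112)]
    front += [(111, string.ascii_uppercase[i]) for i in range(n_front_extra)]
    back = [(112, string.ascii_uppercase[i]) for i in reversed(range(n_back_extra))]
    back += [(n, "") for n in range(112, 118)]
    return front + back


def imgt_number(fv: SequenceRecord, chain_type: str,
                reference_set: list[GermlineRecord],
                min_identity: float = 40.0) -> NumberedFv:
    """Number an Fv sequence on the IMGT frame of its best-matching germline.

    The query is globally aligned to every reference germline (end gaps in
    the germline are free, so CDR3/FR4 tails are not penalised); the frame of
    the highest-identity germline is inherited.  Query residues aligned past
    the germline's last position are numbered as CDR3 (symmetric) followed by
    FR4 (118+).  Identity below ``min_identity`` % to every reference raises.
    """
    if not 80 <= len(fv.residues) <= 140:
        raise ValueError(
            f"{len(fv.residues)} residues is not a plausible V region (80–140)")
    if not reference_set:
        raise ValueError("empty germline reference set")
    aligner = _local_frame_aligner()

    best = None
    for germ in sorted(reference_set, key=lambda g: g.gene_name):
        aln = aligner.align(germ.ungapped, fv.residues)[0]
        ga, qa = str(aln[0]), str(aln[1])
        cols = sum(1 for a, b in zip(ga, qa) if a != "-" and b != "-")
        matches = sum(1 for a, b in zip(ga, qa) if a == b and a != "-")
        identity = 100.0 * matches / cols if cols else 0.0
        if best is None or identity > best[0]:
            best = (identity, germ, ga, qa)
    identity, germ, ga, qa = best
    if identity < min_identity:
        raise ValueError(
            f"best germline identity {identity:.1f}% < {min_identity}%: "
            "not an antibody V region")

    germ_positions = germ.positions
    positions: list[Position] = []
    matched: list[bool] = []
    gi = 0
    pending_insertions = 0
    last_num = 0
    for ca, cb in zip(ga, qa):
        if cb != "-":
            if ca != "-":
                num = germ_positions[gi][0]
                positions.append((num, ""))
                matched.append(True)
                last_num = num
                pending_insertions = 0
            else:
                # insertion relative to the germline frame
                positions.append((last_num, string.ascii_uppercase[pending_insertions]))
                matched.append(False)
                pending_insertions += 1
        if ca != "-":
            gi += 1

    # The CDR3/FR4 tail = query residues past the germline V frame, plus any
    # frame positions the germline itself carries at 105+.  Renumber it with
    # the symmetric CDR3 convention, then FR4 sequentially from 118.
    tail_start = len(positions)
    while tail_start > 0 and not matched[tail_start - 1]:
        tail_start -= 1
    first_cdr3 = next((i for i, p in enumerate(positions) if p[0] >= 105 and not p[1]),
                      None)
    candidates = [i for i in (tail_start, first_cdr3)
                  if i is not None and i < len(positions)]
    cdr3_start_idx = min(candidates) if candidates else None
    if cdr3_start_idx is not None:
        tail_len = len(positions) - cdr3_start_idx
        # FR4 is whatever follows a 13-or-fewer-residue CDR3; without a J
        # reference we cap CDR3 at 13 positions and number the rest 118+.
        cdr3_len = min(tail_len, 13)
        fr4_len = tail_len - cdr3_len
        new_tail = _symmetric_cdr3_positions(cdr3_len)
        new_tail += [(118 + k, "") for k in range(fr4_len)]
        positions = positions[:cdr3_start_idx] + new_tail

    return NumberedFv(chain_type, fv.residues, tuple(positions))


def germline_identity(fv: NumberedFv, germline: GermlineRecord,
                      include_cdr: bool = True) -> float:
    """Percent identity over shared numbered positions (gaps excluded).

    ``include_cdr=False`` restricts the count to framework positions; both
    conventions are offered because printed humanization identities do not
    always state which was used.
    """
    matches = shared = 0
    for pos, letter in zip(fv.imgt_positions, fv.sequence):
        if not include_cdr and cdr_of(pos) is not None:
            continue
        g = germline.residue_at(pos)
        if g is None:
            continue
        shared += 1
        if g == letter:
            matches += 1
    if shared == 0:
        raise ValueError("no shared numbered positions: frame mismatch")
    return 100.0 * matches / shared


def select_germline(fv: NumberedFv,
                    candidates: list[GermlineRecord],
                    include_cdr: bool = True) -> GermlineRecord:
    """FR donor = argmax germline identity; ties broken by gene name."""
    if not candidates:
        raise ValueError("empty candidate set")
    scored = sorted(
        ((germline_identity(fv, g, include_cdr), g) for g in candidates),
        key=lambda t: (-t[0], t[1].gene_name),
    )
    if len(scored) > 1 and scored[0][0] == scored[1][0]:
        import warnings
        warnings.warn(
            f"germline identity tie at {scored[0][0]:.1f}%: choosing "
            f"{scored[0][1].gene_name} by name order", stacklevel=2)
    return scored[0][1]


# Heavy-chain position 59 flanks HCDR2 and is kept parental by default: the
# published graft replaced the donor's S59 with the parental R59 to preserve
# the HCDR2 conformation.
DEFAULT_FLANK_RULES = {"heavy": ((59, ""),), "light": ()}


@dataclass
class GraftResult:
    grafted: NumberedFv
    donor: GermlineRecord
    source_cdrs: dict[str, str]
    flank_substitutions: list[tuple[Position, str, str]]  # (pos, donor aa, parent aa)


def graft_cdrs(parent: NumberedFv, donor: GermlineRecord,
               flank_rules: tuple[Position, ...] | None = None) -> GraftResult:
    """CDR graft: donor frameworks + parental CDRs (+ recorded flank swaps).

    Framework positions take the donor residue where the donor frame covers
    them (positions past the donor V region — CDR3 tail and FR4 — stay
    parental).  Flank-rule positions revert to the parental residue when
    donor and parent differ, and every such swap is recorded.
    """
    if flank_rules is None:
        flank_rules = DEFAULT_FLANK_RULES[parent.chain_type]
    letters = []
    flank_subs: list[tuple[Position, str, str]] = []
    for pos, parent_aa in zip(parent.imgt_positions, parent.sequence):
        donor_aa = donor.residue_at(pos)
        # Flank-rule positions always stay parental and the swap is recorded
        # whenever the donor differs — even when the position sits on a CDR
        # boundary of the numbering scheme.
        if pos in flank_rules and donor_aa is not None and donor_aa != parent_aa:
            letters.append(parent_aa)
            flank_subs.append((pos, donor_aa, parent_aa))
            continue
        if cdr_of(pos) is not None or donor_aa is None:
            letters.append(parent_aa)
        else:
            letters.append(donor_aa)
    grafted = NumberedFv(parent.chain_type, "".join(letters), parent.imgt_positions)
    cdrs = {name: parent.cdr_sequence(name) for name in IMGT_CDR_SPANS}
    return GraftResult(grafted, donor, cdrs, flank_subs)


@dataclass(frozen=True)
class BackMutationThresholds:
    """Heavy-atom distance cutoffs (Å) for the three structural rules."""

    antigen_cutoff: float = 4.5
    pairing_cutoff: float = 4.5
    cdr_cutoff: float = 4.5


@dataclass(frozen=True)
class BackMutation:
    chain_type: str
    imgt_position: Position
    from_aa: str  # humanized (grafted) residue
    to_aa: str    # parental residue
    rationale: str            # primary: first triggered rule
    rationales: tuple[str, ...] = ()  # all triggered rules

    def __str__(self) -> str:
        icode = self.imgt_position[1]
        return f"{self.from_aa}{self.imgt_position[0]}{icode}{self.to_aa}"


@dataclass(frozen=True)
class ChainMap:
    """Where a numbered Fv chain lives in the template structure.

    ``position_map`` converts IMGT positions to template author numbering;
    identity when omitted (templates renumbered on the IMGT frame).
    """

    chain_id: str
    partner_chain_id: str
    antigen_chain_ids: frozenset[str]
    position_map: dict[Position, int] | None = None

    def template_resnum(self, pos: Position) -> int | None:
        if self.position_map is None:
            return pos[0] if not pos[1] else None
        return self.position_map.get(pos)


def _sidechain_atoms(template: Structure, chain_id: str, resnum: int) -> list[Atom]:
    return [a for a in template.atoms
            if a.chain_id == chain_id and a.residue_number == resnum
            and not a.is_mainchain() and a.element != "H"]


def _chain_atoms(template: Structure, chain_ids) -> list[Atom]:
    wanted = {chain_ids} if isinstance(chain_ids, str) else set(chain_ids)
    return [a for a in template.atoms if a.chain_id in wanted and a.element != "H"]


def _min_dist(atoms_a: list[Atom], atoms_b: list[Atom]) -> float:
    import math
    best = float("inf")
    for a in atoms_a:
        for b in atoms_b:
            d = math.dist(a.position, b.position)
            if d < best:
                best = d
    return best


def flag_back_mutations(graft: GraftResult, parent: NumberedFv,
                        template: Structure, chain_map: ChainMap,
                        partner: NumberedFv | None = None,
                        partner_map: ChainMap | None = None,
                        thresholds: BackMutationThresholds = BackMutationThresholds(),
                        ) -> list[BackMutation]:
    """Framework differences worth reverting, judged on the template complex.

    For each framework position where graft and parent differ, the parental
    residue's sidechain in the template is tested, in order, for (i) any
    heavy atom within ``antigen_cutoff`` of the antigen chains
    (``antigen_contact``), (ii) within ``pairing_cutoff`` of the partner V
    domain (``vh_vl_interface``), (iii) within ``cdr_cutoff`` of any CDR
    residue atom of either chain (``cdr_support``).  All triggered rules are
    reported; the primary rationale is the first in that order.
    """
    if not chain_map.antigen_chain_ids:
        raise ValueError("chain_map lacks antigen chain ids")
    antigen_atoms = _chain_atoms(template, chain_map.antigen_chain_ids)
    partner_atoms = _chain_atoms(template, chain_map.partner_chain_id)

    # CDR atoms of this chain and (when mapped) the partner chain.
    cdr_atoms: list[Atom] = []
    for fv, cmap in ((parent, chain_map),
                     (partner, partner_map) if partner is not None else (None, None)):
        if fv is None or cmap is None:
            continue
        for pos in fv.cdr_positions():
            resnum = cmap.template_resnum(pos)
            if resnum is None:
                continue
            cdr_atoms.extend(a for a in template.atoms
                             if a.chain_id == cmap.chain_id
                             and a.residue_number == resnum and a.element != "H")

    out: list[BackMutation] = []
    for pos in parent.imgt_positions:
        if cdr_of(pos) is not None:
            continue
        parent_aa = parent.residue_at(pos)
        graft_aa = graft.grafted.residue_at(pos)
        if graft_aa is None or parent_aa == graft_aa:
            continue
        resnum = chain_map.template_resnum(pos)
        if resnum is None:
            continue
        sc = _sidechain_atoms(template, chain_map.chain_id, resnum)
        if not sc:
            continue
        rationales = []
        if antigen_atoms and _min_dist(sc, antigen_atoms) <= thresholds.antigen_cutoff:
            rationales.append("antigen_contact")
        if partner_atoms and _min_dist(sc, partner_atoms) <= thresholds.pairing_cutoff:
            rationales.append("vh_vl_interface")
        if cdr_atoms:
            non_self = [a for a in cdr_atoms
                        if not (a.chain_id == chain_map.chain_id
                                and a.residue_number == resnum)]
            if non_self and _min_dist(sc, non_self) <= thresholds.cdr_cutoff:
                rationales.append("cdr_support")
        if rationales:
            out.append(BackMutation(parent.chain_type, pos, graft_aa, parent_aa,
                                    rationales[0], tuple(rationales)))
    return out


def build_variant(graft: GraftResult | NumberedFv,
                  mutations: list[BackMutation]) -> NumberedFv:
    """Apply back mutations to a grafted Fv, verifying each starting residue."""
    fv = graft.grafted if isinstance(graft, GraftResult) else graft
    letters = list(fv.sequence)
    for m in mutations:
        try:
            idx = fv.imgt_positions.index(m.imgt_position)
        except ValueError:
            raise ValueError(f"position {m.imgt_position} absent from graft")
        if letters[idx] != m.from_aa:
            raise ValueError(
                f"residue mismatch at IMGT {m.imgt_position[0]}: expected "
                f"{m.from_aa}, found {letters[idx]}")
        letters[idx] = m.to_aa
    return NumberedFv(fv.chain_type, "".join(letters), fv.imgt_positions)
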