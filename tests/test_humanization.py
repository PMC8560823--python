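"""IMGT numbering, germline selection, grafting and back mutations."""

import pytest

from agostruct.humanization import (
    IMGT_CDR_SPANS,
    BackMutation,
    BackMutationThresholds,
    ChainMap,
    GermlineRecord,
    NumberedFv,
    build_variant,
    cdr_of,
    flag_back_mutations,
    germline_identity,
    graft_cdrs,
    imgt_number,
    select_germline,
)
from agostruct.structmodel import Atom, SequenceRecord, Structure
from agostruct.synthetic import make_fv_pair


def _germline(overrides=None, name="SYNV-T*01"):
    """A 104-column synthetic germline frame, default alanine."""
    letters = ["A"] * 104
    for pos, aa in (overrides or {}).items():
        letters[pos - 1] = aa
    return GermlineRecord(name, "synthetic", "".join(letters))


def _fv_from(germline, chain_type="light", overrides=None):
    letters = {p: germline.residue_at(p) for p in germline.positions}
    for pos, aa in (overrides or {}).items():
        letters[(pos, "")] = aa
    positions = tuple(sorted(letters))
    return NumberedFv(chain_type, "".join(letters[p] for p in positions), positions)


# ---------------------------------------------------------------------------
# Numbering

def test_germline_equal_sequence_inherits_its_own_positions():
    parent, germ, _ = make_fv_pair(100, seed=0)
    fv = imgt_number(parent, "heavy", [germ])
    assert fv.imgt_positions == germ.positions


def test_insertion_mid_cdr1_gets_insertion_code_and_frs_unchanged():
    parent, germ, _ = make_fv_pair(100, seed=2)
    idx = next(i for i, p in enumerate(germ.positions) if cdr_of(p) == "CDR1")
    extended = SequenceRecord(
        "ins", parent.residues[:idx + 1] + "W" + parent.residues[idx + 1:],
        tuple((i + 1, "") for i in range(len(parent.residues) + 1)))
    fv = imgt_number(extended, "heavy", [germ])
    inserted = [p for p in fv.imgt_positions if p[1]]
    assert len(inserted) == 1
    assert cdr_of((inserted[0][0], "")) == "CDR1"
    fr = [p for p in fv.imgt_positions if cdr_of(p) is None]
    assert fr == [p for p in germ.positions if cdr_of(p) is None]


def test_cdr3_tail_numbered_symmetrically_from_both_ends():
    parent, germ, _ = make_fv_pair(100, seed=3)
    tail = "WGQGTLVDS"[:9]
    extended = SequenceRecord(
        "cdr3", parent.residues + tail,
        tuple((i + 1, "") for i in range(len(parent.residues) + 9)))
    fv = imgt_number(extended, "heavy", [germ])
    cdr3 = [p for p in fv.imgt_positions if cdr_of(p) == "CDR3"]
    assert [p[0] for p in cdr3] == [105, 106, 107, 108, 109, 114, 115, 116, 117]


def test_dissimilar_sequence_rejected_as_not_v_region():
    germ = _germline()
    query = SequenceRecord("junk", "WYWYWYWYWY" * 10,
                           tuple((i + 1, "") for i in range(100)))
    with pytest.raises(ValueError, match="not an antibody V region"):
        imgt_number(query, "heavy", [germ])


def test_implausible_length_rejected():
    germ = _germline()
    short = SequenceRecord("short", "ACDEFG", tuple((i + 1, "") for i in range(6)))
    with pytest.raises(ValueError, match="plausible V region"):
        imgt_number(short, "heavy", [germ])


def test_point_mutations_never_change_position_labels():
    parent, germ, truth = make_fv_pair(90, seed=4)
    fv = imgt_number(parent, "heavy", [germ])
    exact, _, _ = make_fv_pair(100, seed=4)
    ref = imgt_number(exact, "heavy", [germ])
    assert fv.imgt_positions == ref.imgt_positions


# ---------------------------------------------------------------------------
# Germline identity and selection

@pytest.mark.parametrize("target", [100.0, 66.0, 68.0, 60.0])
def test_identity_matches_designed_target(target):
    parent, germ, truth = make_fv_pair(target, seed=1)
    fv = imgt_number(parent, "heavy", [germ])
    assert germline_identity(fv, germ) == pytest.approx(truth["identity_pct"])


def test_constructed_toy_fifty_positions_thirty_matches():
    germ = _germline()
    overrides = {p: "G" for p in range(70, 90)}  # 20 mismatches over FR3
    fv = _fv_from(germ, overrides=overrides)
    # restrict the count by hand: 104 positions, 20 mismatched
    assert germline_identity(fv, germ) == pytest.approx(100 * 84 / 104)


def test_select_germline_argmax_and_tie_break():
    parent, best, _ = make_fv_pair(66, seed=5)
    fv = imgt_number(parent, "heavy", [best])
    worse1, _, _ = (None, None, None)
    # candidates at lower identity: mutate the germline frame itself
    g60 = GermlineRecord("SYNV-B*01", "synthetic",
                         best.gapped_sequence[:40].replace("A", "G") +
                         best.gapped_sequence[40:])
    chosen = select_germline(fv, [g60, best])
    assert chosen.gene_name == best.gene_name

    twin = GermlineRecord("AAAA-1*01", best.species, best.gapped_sequence)
    with pytest.warns(UserWarning, match="tie"):
        tied = select_germline(fv, [best, twin])
    assert tied.gene_name == "AAAA-1*01"  # lexicographically first


def test_select_germline_empty_candidates_rejected():
    parent, germ, _ = make_fv_pair(100, seed=0)
    fv = imgt_number(parent, "heavy", [germ])
    with pytest.raises(ValueError, match="empty"):
        select_germline(fv, [])


# ---------------------------------------------------------------------------
# Grafting

def test_identity_graft_equals_donor():
    parent, germ, _ = make_fv_pair(100, seed=6)
    fv = imgt_number(parent, "heavy", [germ])
    graft = graft_cdrs(fv, germ, flank_rules=())
    assert graft.grafted.sequence == fv.sequence
    assert graft.flank_substitutions == []


def test_graft_frameworks_from_donor_cdrs_from_parent():
    parent, germ, truth = make_fv_pair(66, seed=7)
    fv = imgt_number(parent, "heavy", [germ])
    graft = graft_cdrs(fv, germ, flank_rules=())
    for pos in graft.grafted.fr_positions():
        assert graft.grafted.residue_at(pos) == germ.residue_at(pos)
    for pos in graft.grafted.cdr_positions():
        assert graft.grafted.residue_at(pos) == fv.residue_at(pos)


def test_hcdr2_flank_rule_keeps_parental_residue_at_59():
    germ = _germline({59: "S"})
    fv = _fv_from(germ, chain_type="heavy", overrides={59: "R"})
    graft = graft_cdrs(fv, germ)  # default heavy flank rules include 59
    assert graft.grafted.residue_at((59, "")) == "R"
    assert graft.flank_substitutions == [((59, ""), "S", "R")]
    # identity bound: donor FRs recovered everywhere outside the flank swap
    fr = graft.grafted.fr_positions()
    assert all(graft.grafted.residue_at(p) == germ.residue_at(p) for p in fr)


def test_marked_cdr_letters_land_only_in_cdr_spans():
    germ = _germline()
    cdr_positions = [p for p in germ.positions if cdr_of(p) is not None]
    fv = _fv_from(germ, overrides={p[0]: "W" for p in cdr_positions})
    graft = graft_cdrs(fv, germ, flank_rules=())
    for pos, aa in zip(graft.grafted.imgt_positions, graft.grafted.sequence):
        assert (aa == "W") == (cdr_of(pos) is not None)


def test_regrafting_parent_cdrs_is_idempotent():
    parent, germ, _ = make_fv_pair(80, seed=8, cdr_marks=True)
    fv = imgt_number(parent, "heavy", [germ])
    once = graft_cdrs(fv, germ, flank_rules=())
    twice = graft_cdrs(once.grafted, germ, flank_rules=())
    assert twice.grafted.sequence == once.grafted.sequence


# ---------------------------------------------------------------------------
# Back mutations

def _bm_template():
    """Template with one framework residue per structural rule.

    Light chain L: position 66 touches the antigen (chain T), position 44
    touches the heavy partner (chain H), position 55 supports CDR2 residue
    57, and position 20 sits far from everything.
    """
    atoms = [
        # L66: sidechain 3 Å from an antigen atom
        Atom("L", 66, "", "ARG", "CA", "C", (0.0, 0.0, 0.0)),
        Atom("L", 66, "", "ARG", "NH1", "N", (1.5, 0.0, 0.0)),
        Atom("T", 705, "", "GLU", "OE1", "O", (4.5, 0.0, 0.0)),
        # L44: sidechain 3 Å from a partner-domain atom
        Atom("L", 44, "", "TYR", "CA", "C", (50.0, 0.0, 0.0)),
        Atom("L", 44, "", "TYR", "OH", "O", (51.5, 0.0, 0.0)),
        Atom("H", 101, "", "TRP", "CZ2", "C", (54.5, 0.0, 0.0)),
        # L55: sidechain 2.5 Å from CDR2 residue 57 of the same chain
        Atom("L", 55, "", "ASP", "CA", "C", (100.0, 0.0, 0.0)),
        Atom("L", 55, "", "ASP", "OD1", "O", (101.5, 0.0, 0.0)),
        Atom("L", 57, "", "ALA", "CA", "C", (104.0, 0.0, 0.0)),
        Atom("L", 57, "", "ALA", "CB", "C", (104.5, 0.0, 0.0)),
        # L20: isolated
        Atom("L", 20, "", "LYS", "CA", "C", (200.0, 0.0, 0.0)),
        Atom("L", 20, "", "LYS", "NZ", "N", (201.5, 0.0, 0.0)),
    ]
    return Structure(atoms)


def _light_pair():
    germ = _germline({20: "E", 44: "F", 55: "Q", 66: "G"})
    parent = _fv_from(germ, overrides={20: "K", 44: "Y", 55: "D", 66: "R"})
    return parent, germ


def test_back_mutation_rules_fire_by_rationale():
    parent, germ = _light_pair()
    graft = graft_cdrs(parent, germ, flank_rules=())
    cmap = ChainMap("L", "H", frozenset({"T"}))
    flags = flag_back_mutations(graft, parent, _bm_template(), cmap)
    by_pos = {m.imgt_position[0]: m for m in flags}
    assert set(by_pos) == {44, 55, 66}
    assert by_pos[66].rationale == "antigen_contact"
    assert by_pos[44].rationale == "vh_vl_interface"
    assert by_pos[55].rationale == "cdr_support"
    assert by_pos[66].from_aa == "G" and by_pos[66].to_aa == "R"


def test_flagged_distances_are_recomputable():
    """Soundness: every emitted flag has a parental sidechain atom within
    its rule's cutoff, checked by direct distance recomputation."""
    import math
    parent, germ = _light_pair()
    graft = graft_cdrs(parent, germ, flank_rules=())
    cmap = ChainMap("L", "H", frozenset({"T"}))
    template = _bm_template()
    thresholds = BackMutationThresholds()
    cut = {"antigen_contact": thresholds.antigen_cutoff,
           "vh_vl_interface": thresholds.pairing_cutoff,
           "cdr_support": thresholds.cdr_cutoff}
    target_chains = {"antigen_contact": {"T"}, "vh_vl_interface": {"H"},
                     "cdr_support": {"L"}}
    for m in flag_back_mutations(graft, parent, template, cmap):
        sc = [a for a in template.atoms if a.chain_id == "L"
              and a.residue_number == m.imgt_position[0] and not a.is_mainchain()]
        others = [a for a in template.atoms
                  if a.chain_id in target_chains[m.rationale]
                  and a.residue_number != m.imgt_position[0]]
        dmin = min(math.dist(a.position, b.position) for a in sc for b in others)
        assert dmin <= cut[m.rationale]


def test_tight_cutoffs_silence_all_rules():
    parent, germ = _light_pair()
    graft = graft_cdrs(parent, germ, flank_rules=())
    cmap = ChainMap("L", "H", frozenset({"T"}))
    flags = flag_back_mutations(graft, parent, _bm_template(), cmap,
                                thresholds=BackMutationThresholds(1.0, 1.0, 1.0))
    assert flags == []


def test_graft_identical_to_parent_flags_nothing():
    parent, germ, _ = make_fv_pair(100, seed=9, chain_type="light")
    fv = imgt_number(parent, "light", [germ])
    graft = graft_cdrs(fv, germ, flank_rules=())
    cmap = ChainMap("L", "H", frozenset({"T"}))
    assert flag_back_mutations(graft, parent=fv, template=_bm_template(),
                               chain_map=cmap) == []


def test_missing_antigen_chains_rejected():
    parent, germ = _light_pair()
    graft = graft_cdrs(parent, germ, flank_rules=())
    with pytest.raises(ValueError, match="antigen"):
        flag_back_mutations(graft, parent, _bm_template(),
                            ChainMap("L", "H", frozenset()))


# ---------------------------------------------------------------------------
# Variant building with the published mutation sets

def _numbered(chain_type, letters_by_pos, n=117):
    letters = ["A"] * n
    for pos, aa in letters_by_pos.items():
        letters[pos - 1] = aa
    return NumberedFv(chain_type, "".join(letters),
                      tuple((i + 1, "") for i in range(n)))


def test_light_chain_back_mutation_set_builds_l2():
    """G34N, Y36L, Q55D, G66R turns the grafted light chain into the
    affinity-restored variant."""
    l1 = _numbered("light", {34: "G", 36: "Y", 55: "Q", 66: "G"})
    muts = [BackMutation("light", (34, ""), "G", "N", "cdr_support"),
            BackMutation("light", (36, ""), "Y", "L", "cdr_support"),
            BackMutation("light", (55, ""), "Q", "D", "cdr_support"),
            BackMutation("light", (66, ""), "G", "R", "antigen_contact")]
    l2 = build_variant(l1, muts)
    assert [l2.residue_at((p, "")) for p in (34, 36, 55, 66)] == ["N", "L", "D", "R"]
    # untouched positions unchanged
    assert l2.residue_at((1, "")) == "A"


def test_heavy_chain_back_mutation_set_builds_h2():
    h1 = _numbered("heavy", {72: "R", 74: "T"})
    muts = [BackMutation("heavy", (72, ""), "R", "V", "cdr_support"),
            BackMutation("heavy", (74, ""), "T", "K", "cdr_support")]
    h2 = build_variant(h1, muts)
    assert h2.residue_at((72, "")) == "V" and h2.residue_at((74, "")) == "K"


def test_empty_mutation_list_leaves_variant_unchanged():
    h1 = _numbered("heavy", {72: "R"})
    assert build_variant(h1, []).sequence == h1.sequence


def test_variant_mismatch_names_the_position():
    l1 = _numbered("light", {34: "G"})
    with pytest.raises(ValueError, match="IMGT 34"):
        build_variant(l1, [BackMutation("light", (34, ""), "Q", "D", "cdr_support")])
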