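import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coibarcode.errors import AmbiguousBaseError, ConfigError
from coibarcode.reference import (
    FOLMER_LENGTH,
    KNOWN_ARTEFACT_LANES,
    REPORTED_GEL_FRAGMENTS,
)
from coibarcode.rflp import (
    IUPAC_EXPAND,
    REGISTRY,
    DigestResult,
    RestrictionEnzyme,
    check_conservation,
    diagnostic_enzymes,
    digest,
    find_sites,
    read_enzyme_tsv,
    reverse_complement,
    to_gel,
)


def naive_find_sites(seq, enz):
    """Independent sliding-window IUPAC matcher (the oracle)."""
    hits = []
    for i in range(len(seq) - len(enz.site) + 1):
        if all(
            seq[i + k] in IUPAC_EXPAND[c] for k, c in enumerate(enz.site)
        ):
            hits.append(i)
    return hits


# ---------------------------------------------------------------------------
# find_sites

def test_find_sites_degenerate_site():
    assert find_sites("GGAATCGG", REGISTRY["HinfI"]) == [1]  # N matches A


def test_find_sites_two_exact_sites():
    assert find_sites("CATGCATG", REGISTRY["NlaIII"]) == [0, 4]


def test_find_sites_no_match():
    for enz in REGISTRY.values():
        assert find_sites("AAAA" * 5, enz) == []


def test_find_sites_overlapping_matches():
    # ScrFI CCNGG: in CCCGGG both windows 0 (CCCGG) and 1 (CCGGG) match
    assert find_sites("CCCGG", REGISTRY["ScrFI"]) == [0]
    assert find_sites("CCCGGG", REGISTRY["ScrFI"]) == [0, 1]


def test_ambiguous_sequence_rejected_with_position():
    with pytest.raises(AmbiguousBaseError, match="position 2"):
        find_sites("ACRT", REGISTRY["NlaIII"])


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=10, max_size=120))
def test_find_sites_matches_naive_oracle(seq):
    for enz in REGISTRY.values():
        assert find_sites(seq, enz) == naive_find_sites(seq, enz)


def test_find_sites_matches_biopython():
    """Cross-check against an established digestion implementation."""
    from Bio.Restriction import HinfI, NlaIII, NlaIV, ScrFI
    from Bio.Seq import Seq

    bio = {"HinfI": HinfI, "NlaIII": NlaIII, "NlaIV": NlaIV, "ScrFI": ScrFI}
    rng = np.random.default_rng(42)
    for _ in range(25):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=654))
        for name, enz in REGISTRY.items():
            ours = digest(seq, enz).cut_positions
            theirs = tuple(p - 1 for p in bio[name].search(Seq(seq)))
            assert ours == theirs, name


# ---------------------------------------------------------------------------
# digest

def test_digest_hinfi_offset():
    r = digest("GGAATCGG", REGISTRY["HinfI"])
    assert r.cut_positions == (2,)
    assert r.fragments == (2, 6)


def test_digest_nlaiii_offset():
    r = digest("ACATGT", REGISTRY["NlaIII"])
    assert r.cut_positions == (5,)
    assert r.fragments == (5, 1)


def test_digest_uncut():
    r = digest("AAAATTTT", REGISTRY["HinfI"])
    assert r.cut_positions == ()
    assert r.fragments == (8,)


def test_digest_boundary_cut_dropped():
    # NlaIII at the very end would cut at position == length: no fragment
    r = digest("ACATG", REGISTRY["NlaIII"])
    assert r.cut_positions == ()
    assert r.fragments == (5,)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=4, max_size=200))
def test_fragment_sum_conservation(seq):
    for enz in REGISTRY.values():
        r = digest(seq, enz)
        assert sum(r.fragments) == len(seq)
        assert len(r.fragments) == len(r.cut_positions) + 1
        assert list(r.cut_positions) == sorted(set(r.cut_positions))


def test_palindromic_site_mirror():
    """A palindromic site occurs at mirrored positions on the reverse
    complement.  For NlaIV the cut bisects the site (GGN^NCC), so the
    fragment multiset is exactly mirrored; for NlaIII the cut sits at
    the site's end (CATG^), so only the site positions mirror exactly
    under top-strand cut modelling."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=300))
        fwd = digest(seq, REGISTRY["NlaIV"]).fragments
        rev = digest(reverse_complement(seq), REGISTRY["NlaIV"]).fragments
        assert sorted(fwd) == sorted(rev)

        sites_fwd = find_sites(seq, REGISTRY["NlaIII"])
        sites_rev = find_sites(reverse_complement(seq), REGISTRY["NlaIII"])
        assert sites_rev == sorted(len(seq) - 4 - p for p in sites_fwd)


# ---------------------------------------------------------------------------
# conservation of the reported assay patterns

def test_reported_patterns_conservation():
    for lane, fragments in REPORTED_GEL_FRAGMENTS.items():
        ok = check_conservation(fragments, FOLMER_LENGTH)
        assert ok == (lane not in KNOWN_ARTEFACT_LANES), lane


# ---------------------------------------------------------------------------
# gel projection

def test_gel_two_clean_bands():
    r = DigestResult("HinfI", "Q", (73,), (73, 581))
    assert to_gel(r).bands == (581, 73)


def test_gel_merge_and_drop_rules():
    # 31 < min_visible dropped; 101 within 20 of 114 co-migrates;
    # 195 within 20 of 213 co-migrates under the same rule
    r = DigestResult("HinfI", "Z", (0,), (31, 101, 114, 195, 213))
    assert to_gel(r, resolution=20, min_visible=40).bands == (213, 114)


def test_gel_uncut_single_band():
    r = DigestResult("x", "h", (), (654,))
    assert to_gel(r).bands == (654,)


def test_gel_band_spacing_invariant():
    rng = np.random.default_rng(3)
    for _ in range(50):
        frags = tuple(int(x) for x in rng.integers(10, 600, size=6))
        g = to_gel(DigestResult("e", "h", (), frags), 20, 40)
        assert all(b >= 40 for b in g.bands)
        assert all(a - b > 20 for a, b in zip(g.bands, g.bands[1:]))


# ---------------------------------------------------------------------------
# diagnostic enzyme ranking

def dr(enzyme, fragments, hap="h"):
    return DigestResult(enzyme, hap, (), tuple(fragments))


def test_two_vs_five_fragment_patterns_are_diagnostic():
    reports = diagnostic_enzymes(
        {"HinfI": [dr("HinfI", (73, 581), "Q1")]},
        {"HinfI": [dr("HinfI", (31, 101, 114, 195, 213), "Z1")]},
    )
    assert reports[0].diagnostic


def test_identical_patterns_not_diagnostic():
    reports = diagnostic_enzymes(
        {"E": [dr("E", (100, 554), "Q1")]},
        {"E": [dr("E", (100, 554), "Z1")]},
    )
    assert not reports[0].diagnostic


def test_multi_variant_enzyme_ranks_below_single_variant():
    """An enzyme whose B-species shows three pattern variants is still
    diagnostic but ranks below an equally diagnostic single-variant one."""
    clean = {
        "CleanE": [dr("CleanE", (73, 581), "Q1")],
    }
    clean_b = {
        "CleanE": [
            dr("CleanE", (213, 441), "Z1"),
            dr("CleanE", (213, 441), "Z2"),
        ],
    }
    messy = {
        "MessyE": [dr("MessyE", (70, 79, 211, 294), "Q1")],
    }
    messy_b = {
        "MessyE": [
            dr("MessyE", (91, 120, 150, 293), "Z1"),
            dr("MessyE", (91, 150, 413), "Z3"),
            dr("MessyE", (91, 150, 200, 413), "Z5"),
        ],
    }
    reports = diagnostic_enzymes(
        {**clean, **messy}, {**clean_b, **messy_b}
    )
    assert [r.enzyme for r in reports] == ["CleanE", "MessyE"]
    assert all(r.diagnostic for r in reports)
    assert reports[1].n_variants_b == 3


def test_empty_group_rejected():
    with pytest.raises(ConfigError):
        diagnostic_enzymes({"E": []}, {"E": [dr("E", (654,))]})


# ---------------------------------------------------------------------------
# registry

def test_registry_contents():
    spec = {
        "HinfI": ("GANTC", 1),
        "NlaIII": ("CATG", 4),
        "NlaIV": ("GGNNCC", 3),
        "ScrFI": ("CCNGG", 2),
    }
    assert {k: (v.site, v.cut_offset) for k, v in REGISTRY.items()} == spec


def test_enzyme_validation():
    with pytest.raises(ConfigError):
        RestrictionEnzyme("bad", "GAT", 1)  # too short
    with pytest.raises(ConfigError):
        RestrictionEnzyme("bad", "GATC", 9)  # offset out of range


def test_enzyme_tsv_extension(tmp_path):
    p = tmp_path / "enzymes.tsv"
    p.write_text("name\tsite\toffset\nEcoRI\tGAATTC\t1\n")
    reg = read_enzyme_tsv(p)
    assert reg["EcoRI"].site == "GAATTC"
    assert set(REGISTRY) <= set(reg)
    assert digest("AGAATTCA", reg["EcoRI"]).fragments == (2, 6)
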