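"""Fragment design, binding-site delineation and repeat scanning."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from relaxkit.errors import ConfigError
from relaxkit.oritmap import (ShiftCall, delineate_site, find_direct_repeats,
                              find_inverted_repeats, interval_length,
                              make_fragments)
from relaxkit.seqio import reverse_complement

DNA = st.text(alphabet="ACGT", min_size=1, max_size=60)


@pytest.mark.parametrize("region,expected_n", [(500, 13), (200, 1), (450, 11)])
def test_fragment_counts(region, expected_n):
    fs = make_fragments(region, 200, 25)
    assert len(fs.fragments) == expected_n


def test_fragment_labels_and_geometry():
    fs = make_fragments(500, 200, 25, first_label=21)
    assert fs.labels() == [f"F{i}" for i in range(21, 34)]
    assert all(f.end - f.start + 1 == 200 for f in fs.fragments)
    starts = [f.start for f in fs.fragments]
    assert all(b - a == 25 for a, b in zip(starts, starts[1:]))


def test_invalid_step_rejected():
    with pytest.raises(ConfigError):
        make_fragments(500, 200, 0)


def _calls(positive, all_labels):
    return [ShiftCall(lab, "strong" if lab in positive else "none")
            for lab in all_labels]


def test_delineate_f22_f29_shares_25_bp():
    """Eight consecutive positives in the 200/25 design share 200-7*25 = 25 bp."""
    fs = make_fragments(500, 200, 25)
    pos = {f"F{i}" for i in range(22, 30)}
    site = delineate_site(fs, _calls(pos, fs.labels()), {"strong"})
    assert interval_length(site) == 25
    assert site == (fs["F29"].start, fs["F22"].end)


def test_delineate_f21_f25_strong_is_100_bp():
    fs = make_fragments(500, 200, 25)
    pos = {f"F{i}" for i in range(21, 26)}
    site = delineate_site(fs, _calls(pos, fs.labels()), {"strong"})
    assert interval_length(site) == 200 - 4 * 25


def test_delineate_single_fragment_returns_its_interval():
    fs = make_fragments(500, 200, 25)
    site = delineate_site(fs, _calls({"F23"}, fs.labels()), {"strong"})
    assert site == (fs["F23"].start, fs["F23"].end)


def test_delineate_no_positive_fragment_is_empty():
    fs = make_fragments(500, 200, 25)
    assert delineate_site(fs, _calls(set(), fs.labels()), {"strong"}) is None


def test_delineate_disjoint_fragments_is_empty():
    fs = make_fragments(500, 200, 25)
    site = delineate_site(fs, _calls({"F21", "F33"}, fs.labels()), {"strong"})
    assert site is None  # F21 ends at 200, F33 starts at 301


def test_outcome_filter_selects_weak_and_strong_separately():
    fs = make_fragments(500, 200, 25)
    calls = [ShiftCall(f"F{i}", "strong") for i in range(21, 26)] + \
            [ShiftCall(f"F{i}", "weak") for i in range(26, 29)] + \
            [ShiftCall(f"F{i}", "none") for i in range(29, 34)]
    strong = delineate_site(fs, calls, {"strong"})
    both = delineate_site(fs, calls, {"strong", "weak"})
    assert interval_length(strong) == 100
    assert interval_length(both) == 200 - 7 * 25


def test_delineation_agrees_with_per_base_intersection():
    """Oracle: interval intersection equals a brute-force per-base membership
    count over every fragment subset of size <= 3 plus consecutive runs."""
    fs = make_fragments(500, 200, 25)
    labels = fs.labels()
    subsets = list(itertools.combinations(labels, 2)) + \
        list(itertools.combinations(labels, 3)) + \
        [tuple(labels[i:j]) for i in range(len(labels))
         for j in range(i + 1, len(labels) + 1)]
    for subset in subsets:
        site = delineate_site(fs, _calls(set(subset), labels), {"strong"})
        covered = [set(range(fs[lab].start, fs[lab].end + 1)) for lab in subset]
        common = set.intersection(*covered)
        if site is None:
            assert common == set()
        else:
            assert common == set(range(site[0], site[1] + 1))


def brute_force_palindromes(seq, min_len):
    """Definitional check: maximal substrings with p == revcomp(p)."""
    found = []
    n = len(seq)
    for i in range(n):
        for j in range(i + min_len, n + 1):
            p = seq[i:j]
            if len(p) % 2 == 0 and p == reverse_complement(p):
                extendable = (i > 0 and j < n and
                              seq[i - 1:j + 1] ==
                              reverse_complement(seq[i - 1:j + 1]))
                if not extendable:
                    found.append((i + 1, j - i, p))
    return sorted(found)


def test_shared_25bp_sequence_contains_the_palindrome():
    shared = "CAAATAAATCTGGTACCACGAAAAA"
    hits = find_inverted_repeats(shared, min_len=8)
    assert any(h.motif == "TGGTACCA" for h in hits)


def test_ecori_site_is_palindrome():
    hits = find_inverted_repeats("GAATTC", min_len=6)
    assert hits == [hit for hit in hits if hit.motif == "GAATTC"]
    assert len(hits) == 1


def test_homopolymer_has_no_palindrome():
    assert find_inverted_repeats("AAAAAA", min_len=2) == []


@settings(max_examples=300, deadline=None, derandomize=True)
@given(DNA)
def test_palindrome_finder_equals_exhaustive_enumeration(seq):
    got = sorted((h.start, h.length, h.motif)
                 for h in find_inverted_repeats(seq, min_len=2))
    assert got == brute_force_palindromes(seq, 2)


def test_direct_repeat_hand_count():
    hits = find_direct_repeats("TGTGCATTGTGCAT", motif="TGTGCAT")
    assert [h.start for h in hits] == [1, 8]


def test_direct_repeat_absent_motif():
    assert find_direct_repeats("ACGTACGT", motif="TTTTT") == []


def test_direct_repeat_overlapping_occurrences():
    hits = find_direct_repeats("ATATATA", motif="ATA")
    assert [h.start for h in hits] == [1, 3, 5]


def test_de_novo_kmer_mode():
    table = find_direct_repeats("TGTGCATTTGTGCAT", k=7, min_count=2)
    assert table["TGTGCAT"] == [1, 9]


def test_scan_strand_consistency():
    """Occurrences of revcomp(motif) on revcomp(seq) mirror positions."""
    seq = "CCTGTGCATAATGTGCATGG"
    motif = "TGTGCAT"
    fwd = [h.start for h in find_direct_repeats(seq, motif=motif)]
    rev = [h.start for h in find_direct_repeats(reverse_complement(seq),
                                                motif=reverse_complement(motif))]
    mirrored = sorted(len(seq) - (p + len(motif) - 1) + 1 for p in fwd)
    assert sorted(rev) == mirrored
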