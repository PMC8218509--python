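"""Enriched-string construction: splicing, markers, and the weight identity."""

import re

import pytest

from esskit import (
    CanonicalKmerSet,
    ess_compress,
    extract_kmers,
    predicted_weight,
    spss_to_kmers,
)
from esskit.decoder import decode_result
from esskit.encoder import encode_cover, read_ess, write_ess
from esskit.errors import FormatError

from conftest import noisy_kmer_set, random_kmer_set


def test_toy_absorb_matches_printed_encoding(fixtures):
    f = fixtures["toy_absorb"]
    r = encode_cover(f.graph, f.cover, mode="ess")
    assert r.strings == ("TCGT[+AA]T",)
    assert r.weight == 10 == r.predicted_weight
    assert r.num_paths == 2 and r.n_sc == 1


def test_recursive_absorption_nests_brackets(fixtures):
    f = fixtures["recursive3"]
    r = encode_cover(f.graph, f.cover, f.forest, mode="ess")
    assert r.strings == ("AAACC[+G[+T]]",)
    assert spss_to_kmers(decode_result(r)).kmers == f.graph.vertices


def test_single_unitig_no_absorption():
    r = ess_compress(CanonicalKmerSet.from_kmers(["AAC", "ACC"]))
    assert r.strings == ("AACC",)
    assert r.weight == 4 == predicted_weight(2, 1, 1, 3)


def test_predicted_weight_formula():
    assert predicted_weight(5, 2, 1, 3) == 10  # the printed example's character count
    assert predicted_weight(2, 1, 1, 3) == 4
    # no-absorption limit reduces to the cover weight |K| + |Psi|(k-1)
    for n, psi, k in [(10, 4, 7), (33, 5, 21)]:
        assert predicted_weight(n, psi, psi, k) == n + psi * (k - 1)
    with pytest.raises(ValueError):
        predicted_weight(5, 2, 3, 7)


@pytest.mark.parametrize("seed", range(30))
def test_weight_identity_on_random_sets(seed):
    K = random_kmer_set(seed)
    if K is None:
        pytest.skip("degenerate draw")
    r = ess_compress(K)  # raises internally if the identity fails
    assert r.weight == predicted_weight(r.num_kmers, r.num_paths, r.n_sc, K.k)
    assert r.weight == sum(r.per_path_chars.values())


def test_each_absorption_saves_k_minus_4():
    K = noisy_kmer_set(3, k=15, genome_length=1_500)
    r = ess_compress(K)
    assert r.num_absorbed > 0  # error-rich graphs absorb
    assert r.spss_weight - r.weight == (K.k - 4) * r.num_absorbed
    assert r.weight < r.spss_weight  # strict, since k > 4 and absorptions happened


def test_marker_count_equals_absorbed_paths():
    K = noisy_kmer_set(5, k=15, genome_length=1_500)
    r = ess_compress(K)
    n_markers = sum(s.count("+") + s.count("-") for s in r.strings)
    assert n_markers == r.num_paths - r.n_sc == r.num_absorbed


def test_bracket_groups_well_formed():
    """Balanced brackets; every group starts with exactly one top-level marker."""
    K = noisy_kmer_set(7, k=15, genome_length=1_500)
    r = ess_compress(K)
    for s in r.strings:
        depth = 0
        expects_marker = False
        for ch in s:
            if ch == "[":
                depth += 1
                expects_marker = True
            elif ch == "]":
                depth -= 1
                assert depth >= 0
            elif ch in "+-":
                assert expects_marker, "marker outside a bracket-group head"
                expects_marker = False
            else:
                assert not expects_marker, "bracket group must open with a marker"
        assert depth == 0
        # roots never carry a marker at their own level
        assert re.sub(r"\[[^]]*", "", s).replace("]", "").strip("ACGT") == ""


def test_number_of_strings_equals_n_sc():
    for seed in range(5):
        K = noisy_kmer_set(seed, k=13, genome_length=800)
        r = ess_compress(K)
        assert len(r.strings) == r.n_sc


def test_ess_file_round_trip(tmp_path):
    K = noisy_kmer_set(2, k=11, genome_length=500)
    r = ess_compress(K)
    path = tmp_path / "out.ess"
    write_ess(r, path)
    first = path.read_text().splitlines()[0]
    assert first == f"#ESS\tv1\tk=11\tmode=ess\tn={len(r.strings)}"
    k, mode, strings = read_ess(path)
    assert (k, mode, tuple(strings)) == (11, "ess", r.strings)


def test_ess_file_rejects_garbled_header(tmp_path):
    path = tmp_path / "bad.ess"
    path.write_text("#ESS\tv1\tk=eleven\tmode=ess\tn=0\n")
    with pytest.raises(FormatError):
        read_ess(path)
    path.write_text("ACGT\n")
    with pytest.raises(FormatError):
        read_ess(path)
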