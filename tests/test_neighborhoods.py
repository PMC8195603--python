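"""Neighborhood extraction, validity filters, and conserved-group recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contextscan.genome_model import Gene
from contextscan.neighborhoods import (
    Neighborhood,
    anchor_by_domain,
    apply_validity_filters,
    extract_neighborhoods,
    scan_genomes,
)
from contextscan.synthetic_data import SyntheticConfig, generate_genomes

from conftest import make_genome


def chain_genome(gaps, strands=None, anchor_idx=0, seqs=None):
    """Genome of consecutive genes with the given intergenic gaps (gap[i] is
    between gene i and gene i+1); gene length fixed at 300 nt."""
    n = len(gaps) + 1
    strands = strands or ["+"] * n
    genes = []
    pos = 100
    for i in range(n):
        seq = seqs[i] if seqs else "M" + "A" * 99
        arch = ("Anc",) if i == anchor_idx else ()
        genes.append((f"g{i}", pos, pos + 299, strands[i], seq, arch))
        if i < len(gaps):
            pos = pos + 299 + gaps[i] + 1
    return make_genome("t1", "P", genes)


class TestExtract:
    def test_mid_replicon_window_two_gives_five_members(self):
        g = chain_genome([10, 10, 10, 10], anchor_idx=2)
        (n,) = extract_neighborhoods(g, anchor_by_domain("Anc"), window=2)
        assert len(n.members) == 5
        assert n.anchor == "g2"

    def test_replicon_start_truncates_without_wraparound(self):
        g = chain_genome([10, 10, 10, 10], anchor_idx=0)
        (n,) = extract_neighborhoods(g, anchor_by_domain("Anc"), window=2)
        assert len(n.members) == 3
        assert [m.gene_id for m in n.members] == ["g0", "g1", "g2"]

    def test_predicate_matching_nothing_gives_empty_list(self):
        g = chain_genome([10, 10])
        assert extract_neighborhoods(g, anchor_by_domain("Missing"), window=2) == []

    def test_window_must_be_positive(self):
        g = chain_genome([10])
        with pytest.raises(ValueError):
            extract_neighborhoods(g, anchor_by_domain("Anc"), window=0)


class TestValidityFilters:
    def test_gap_over_threshold_stops_the_walk(self):
        """Downstream gaps [10, 60, 5]: only the first downstream gene survives."""
        g = chain_genome([10, 60, 5], anchor_idx=0)
        (n,) = extract_neighborhoods(g, anchor_by_domain("Anc"), window=3)
        trimmed, flags = apply_validity_filters(n, max_gap_nt=50)
        assert [m.gene_id for m in trimmed.members] == ["g0", "g1"]
        assert flags.distance_trimmed == ("g2", "g3")

    def test_nothing_trimmed_when_all_pass(self):
        g = chain_genome([10, 20, 30], anchor_idx=1)
        (n,) = extract_neighborhoods(g, anchor_by_domain("Anc"), window=3)
        trimmed, flags = apply_validity_filters(n, max_gap_nt=50)
        assert trimmed.members == n.members
        assert flags.distance_trimmed == () and flags.strand_trimmed == ()

    def test_gap_of_exactly_fifty_is_retained(self):
        g = chain_genome([50], anchor_idx=0)
        (n,) = extract_neighborhoods(g, anchor_by_domain("Anc"), window=1)
        trimmed, _ = apply_validity_filters(n, max_gap_nt=50)
        assert len(trimmed.members) == 2

    def test_overlapping_gene_always_retained(self):
        g = chain_genome([-20], anchor_idx=0)
        (n,) = extract_neighborhoods(g, anchor_by_domain("Anc"), window=1)
        trimmed, _ = apply_validity_filters(n, max_gap_nt=0)
        assert len(trimmed.members) == 2

    def test_strand_filter_compares_to_anchor(self):
        g = chain_genome([10, 10], strands=["+", "-", "+"], anchor_idx=0)
        (n,) = extract_neighborhoods(g, anchor_by_domain("Anc"), window=2)
        trimmed, flags = apply_validity_filters(n, require_codirectional=True)
        assert [m.gene_id for m in trimmed.members] == ["g0"]
        assert flags.strand_trimmed == ("g1", "g2")
        keep_all, _ = apply_validity_filters(n, require_codirectional=False)
        assert len(keep_all.members) == 3

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        gaps=st.lists(st.integers(min_value=-25, max_value=120), min_size=1,
                      max_size=6),
        threshold=st.integers(min_value=0, max_value=120),
    )
    def test_trimming_is_monotone_in_max_gap(self, gaps, threshold):
        """Raising the gap threshold never removes a retained member."""
        g = chain_genome(gaps, anchor_idx=0)
        (n,) = extract_neighborhoods(g, anchor_by_domain("Anc"), window=len(gaps))
        tight, _ = apply_validity_filters(n, max_gap_nt=threshold)
        loose, _ = apply_validity_filters(n, max_gap_nt=threshold + 30)
        tight_ids = {m.gene_id for m in tight.members}
        loose_ids = {m.gene_id for m in loose.members}
        assert tight_ids <= loose_ids


class TestConservedGroups:
    def test_planted_cassette_recovered_exactly(self):
        cfg = SyntheticConfig(n_taxa=10, carriers_per_cassette=6,
                              phyla_per_cassette=3, family_divergence=0.1,
                              genes_per_replicon=(15, 25), seed=21)
        genomes, truth = generate_genomes(cfg)
        groups = scan_genomes(genomes, "AnchorDom", window=2)
        assert len(groups) == 1
        (grp,) = groups
        assert grp.taxa == frozenset(truth.cassettes[0].carrier_taxa)
        assert grp.phyla == frozenset(truth.cassettes[0].phyla)
        assert len(grp.member_neighborhoods) == 6

    def test_single_phylum_cassette_yields_no_groups(self):
        cfg = SyntheticConfig(n_taxa=8, carriers_per_cassette=4,
                              phyla_per_cassette=1, genes_per_replicon=(15, 25),
                              seed=22)
        genomes, _ = generate_genomes(cfg)
        assert scan_genomes(genomes, "AnchorDom", window=2) == []

    def test_unrelated_anchors_never_merge(self):
        """Two cassettes built from unrelated families give two groups."""
        cfg = SyntheticConfig(n_taxa=10, n_cassettes=2, carriers_per_cassette=4,
                              phyla_per_cassette=2, genes_per_replicon=(15, 25),
                              n_decoy_anchors=0, seed=23)
        genomes, truth = generate_genomes(cfg)
        groups = scan_genomes(genomes, "AnchorDom", window=2)
        assert len(groups) == 2
        group_taxa = sorted(sorted(g.taxa) for g in groups)
        planted_taxa = sorted(sorted(c.carrier_taxa) for c in truth.cassettes)
        assert group_taxa == planted_taxa

    def test_missing_sequence_errors_naming_anchor(self):
        g = make_genome("t1", "P", [("g0", 100, 399, "+", None, ("Anc",))])
        (n,) = extract_neighborhoods(g, anchor_by_domain("Anc"), window=1)
        from contextscan.neighborhoods import find_conserved_groups
        with pytest.raises(ValueError, match="g0"):
            find_conserved_groups([n], {"t1": g})

    def test_output_invariant_to_genome_order(self):
        cfg = SyntheticConfig(n_taxa=8, carriers_per_cassette=4,
                              phyla_per_cassette=2, genes_per_replicon=(12, 18),
                              seed=24)
        genomes, _ = generate_genomes(cfg)
        fwd = scan_genomes(genomes, "AnchorDom", window=2)
        rev = scan_genomes(list(reversed(genomes)), "AnchorDom", window=2)
        assert [sorted(g.taxa) for g in fwd] == [sorted(g.taxa) for g in rev]


def test_neighborhood_anchor_must_be_member():
    g = Gene("a", "chr", 1, 10, "+")
    with pytest.raises(ValueError):
        Neighborhood("missing", "t", "chr", (g,), 1)
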