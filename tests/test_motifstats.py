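"""Trimer enrichment, E-site codon bias, asymmetry and dependency calls."""

import math

import numpy as np
import pytest

from ribostall.models import (
    DependencyLabel,
    GeneModel,
    PauseSite,
)
from ribostall.motifstats import (
    asymmetry_score,
    dependency_call,
    esite_first_nt_bias,
    ribosome_trimer,
    trimer_enrichment,
)

from conftest import make_profile


def gene_from_aa(aa_seq, codon_choice=None, gene_id="g1"):
    """Build a CDS realizing an amino-acid sequence (first codon per aa)."""
    from ribostall.models import AA_TO_CODONS

    codons = []
    for i, aa in enumerate(aa_seq):
        if codon_choice and i in codon_choice:
            codons.append(codon_choice[i])
        else:
            codons.append(AA_TO_CODONS[aa][0])
    return GeneModel.from_cds(gene_id, "".join(codons))


class TestRibosomeTrimer:
    def test_epa_convention(self):
        gene = gene_from_aa("MKPPNF")
        assert ribosome_trimer(gene, 4) == "PPN"

    def test_another_trimer(self):
        gene = gene_from_aa("MGDPAK")
        assert ribosome_trimer(gene, 4) == "DPA"

    def test_near_start_undefined(self):
        gene = gene_from_aa("MKPPNF")
        assert ribosome_trimer(gene, 1) is None

    def test_stop_containing_trimer_undefined(self):
        gene = gene_from_aa("MKPPN*")
        assert ribosome_trimer(gene, 5) is None


def brute_force_enrichment(pause_sites, profiles, genes):
    """Independent tally of pause and occupancy-weighted frequencies."""
    by_id = {g.gene_id: g for g in genes}
    pause, background = {}, {}
    for s in pause_sites:
        t = ribosome_trimer(by_id[s.gene_id], s.asite_codon)
        if t is not None:
            pause[t] = pause.get(t, 0) + 1
    for gene_id, p in profiles.items():
        for codon, count in enumerate(p.codon_counts):
            t = ribosome_trimer(by_id[gene_id], int(codon))
            if t is not None and count:
                background[t] = background.get(t, 0) + int(count)
    np_, nb = sum(pause.values()), sum(background.values())
    out = {}
    for t in set(pause) | set(background):
        fp = pause.get(t, 0) / np_
        fb = background.get(t, 0) / nb
        out[t] = (fp, fb, fp / fb if fb else math.inf)
    return out


class TestTrimerEnrichment:
    def test_toy_example_enrichment_of_twenty(self):
        """All pause sites carry one trimer that holds 5% of the
        occupancy: enrichment 1.0/0.05 = 20."""
        gene = gene_from_aa("MA" + "PPN" + "GLV" * 5 + "W*")
        counts = np.zeros(gene.n_codons, dtype=int)
        counts[4] = 5   # A-site on N of PPN: 5% of the occupancy weight
        counts[5] = 95  # the rest sits on the PNG trimer
        nt = np.zeros(3 * gene.n_codons, dtype=int)
        nt[::3] = counts
        profiles = {"g1": make_profile(nt)}
        sites = [PauseSite("g1", 12 + i, 4, 50.0, 1.0) for i in range(10)]
        records = trimer_enrichment(sites, profiles, [gene])
        by_trimer = {r.trimer: r for r in records}
        assert by_trimer["PPN"].freq_pause == pytest.approx(1.0)
        assert by_trimer["PPN"].freq_background == pytest.approx(0.05)
        assert by_trimer["PPN"].enrichment == pytest.approx(20.0)

    def test_absent_trimer_has_zero_enrichment(self):
        gene = gene_from_aa("MAPPNGLVW*")
        nt = np.zeros(3 * gene.n_codons, dtype=int)
        nt[::3][4:8] = 10
        profiles = {"g1": make_profile(nt)}
        sites = [PauseSite("g1", 12, 4, 50.0, 1.0)]
        records = trimer_enrichment(sites, profiles, [gene])
        by_trimer = {r.trimer: r for r in records}
        assert by_trimer["NGL"].freq_pause == 0.0
        assert by_trimer["NGL"].enrichment == 0.0

    def test_frequencies_sum_to_one(self, rng):
        genes, profiles, sites = _random_instance(rng, n_genes=4)
        records = trimer_enrichment(sites, profiles, genes)
        assert sum(r.freq_pause for r in records) == pytest.approx(1.0, abs=1e-9)
        assert sum(r.freq_background for r in records) == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_tally(self, rng):
        for _ in range(20):
            genes, profiles, sites = _random_instance(rng, n_genes=3)
            records = trimer_enrichment(sites, profiles, genes)
            expected = brute_force_enrichment(sites, profiles, genes)
            assert {r.trimer for r in records} == set(expected)
            for r in records:
                fp, fb, rho = expected[r.trimer]
                assert r.freq_pause == pytest.approx(fp, abs=1e-9)
                assert r.freq_background == pytest.approx(fb, abs=1e-9)
                assert r.enrichment == pytest.approx(rho, abs=1e-9) or (
                    math.isinf(rho) and math.isinf(r.enrichment)
                )

    def test_background_sampled_sites_are_unenriched(self, rng):
        """Pause sites drawn from the background occupancy itself show
        enrichment ~1 for every sampled trimer (resampling oracle)."""
        genes, profiles, _ = _random_instance(rng, n_genes=2, n_codons=400)
        gene = genes[0]
        counts = profiles[gene.gene_id].codon_counts
        eligible = [c for c in range(2, gene.n_codons)
                    if ribosome_trimer(gene, c) and counts[c] > 0]
        weights = np.array([counts[c] for c in eligible], dtype=float)
        draws = rng.choice(eligible, size=4000, p=weights / weights.sum())
        sites = [PauseSite(gene.gene_id, 3 * int(c), int(c), 30.0, 1.0) for c in draws]
        records = trimer_enrichment(sites, {gene.gene_id: profiles[gene.gene_id]}, [gene])
        seen = [r for r in records if r.freq_pause > 0.005]
        for r in seen:
            n = r.freq_pause * len(draws)
            tol = 4 * math.sqrt(n) / len(draws) / max(r.freq_background, 1e-9)
            assert abs(r.enrichment - 1.0) <= tol


def _random_instance(rng, n_genes=3, n_codons=60):
    from conftest import random_cds

    genes = [GeneModel.from_cds(f"g{i + 1}", random_cds(rng, n_codons))
             for i in range(n_genes)]
    profiles = {}
    sites = []
    for g in genes:
        nt = np.zeros(3 * n_codons, dtype=int)
        nt[::3] = rng.integers(0, 8, size=n_codons)
        profiles[g.gene_id] = make_profile(nt, gene_id=g.gene_id)
        for c in rng.integers(0, n_codons, size=3):
            sites.append(PauseSite(g.gene_id, 3 * int(c), int(c), 25.0, 1.0))
    # ensure at least one defined trimer
    sites.append(PauseSite(genes[0].gene_id, 30, 10, 25.0, 1.0))
    return genes, profiles, sites


class TestEsiteBias:
    def test_all_gat_codons_give_full_g_fraction(self):
        gene = gene_from_aa("MA" + "DPN" * 5 + "*", codon_choice={i: "GAT" for i in (2, 5, 8, 11, 14)})
        sites = [PauseSite("g1", 0, c, 30.0, 1.0) for c in (4, 7, 10, 13, 16)]
        matrix, g_fraction = esite_first_nt_bias(sites, [gene])
        assert g_fraction == 1.0
        np.testing.assert_allclose(matrix.sum(axis=1), 1.0)

    def test_mixed_codons_direct_count(self):
        # E-site codons GAT, GAA, CCG, GTT -> G fraction 0.75
        choice = {2: "GAT", 5: "GAA", 8: "CCG", 11: "GTT"}
        gene = gene_from_aa("MA" + "DPN" + "EPN" + "PPN" + "VPN" + "*", codon_choice=choice)
        sites = [PauseSite("g1", 0, c, 30.0, 1.0) for c in (4, 7, 10, 13)]
        _, g_fraction = esite_first_nt_bias(sites, [gene])
        assert g_fraction == 0.75

    def test_requires_eligible_sites(self):
        gene = gene_from_aa("MKPPNF")
        with pytest.raises(ValueError):
            esite_first_nt_bias([PauseSite("g1", 0, 1, 30.0, 1.0)], [gene])


class TestAsymmetryScore:
    def test_symmetric_flat_profile_scores_one(self):
        nt = np.zeros(90, dtype=int)
        nt[::3] = 4
        result = asymmetry_score(make_profile(nt), (14, 16), flank=10, pseudocount=0.0)
        assert result.asymmetry_score == pytest.approx(1.0)

    def test_direct_arithmetic_example(self):
        counts = np.zeros(150, dtype=int)
        counts[3 * 10 : 3 * 20 : 3] = 10   # upstream flank sum 100
        counts[3 * 23 : 3 * 33 : 3] = 2    # downstream flank sum 20
        result = asymmetry_score(make_profile(counts), (20, 23), flank=10, pseudocount=0.5)
        assert result.upstream_sum == 100
        assert result.downstream_sum == 20
        assert result.asymmetry_score == pytest.approx(20.5 / 100.5)

    def test_scale_invariance_without_pseudocount(self, rng):
        nt = np.zeros(300, dtype=int)
        nt[::3] = rng.integers(1, 9, size=100)
        a = asymmetry_score(make_profile(nt), (40, 43), flank=20, pseudocount=0.0)
        b = asymmetry_score(make_profile(nt * 5), (40, 43), flank=20, pseudocount=0.0)
        assert a.asymmetry_score == pytest.approx(b.asymmetry_score, abs=1e-9)

    def test_flank_clipping_minimum(self):
        nt = np.ones(60, dtype=int)
        with pytest.raises(ValueError):
            asymmetry_score(make_profile(nt), (2, 5), flank=25)

    def test_simulated_dropoff_recovered(self):
        """Drop-off d=0.5 downstream of a planted motif yields AS ~ 0.5."""
        from ribostall.occupancy import build_profiles
        from ribostall.simdata import (
            PlantedMotif, SimConfig, make_transcriptome, simulate_footprints,
        )

        cfg = SimConfig(
            n_genes=1, gene_len_codons=200, depth=50.0, dup_rate=0.0, seed=51,
            planted_motifs=[PlantedMotif("g1", 100, "DPN", 50.0, dropoff_prob=0.5)],
        )
        genes = make_transcriptome(cfg)
        _, alignments, _ = simulate_footprints(genes, cfg)
        profiles = build_profiles(alignments, genes, offset=cfg.asite_offset)
        result = asymmetry_score(profiles["g1"], (98, 101), flank=25)
        assert result.asymmetry_score == pytest.approx(0.5, rel=0.15)


class TestDependencyCall:
    @pytest.mark.parametrize(
        "as_wt,as_mut,expected",
        [
            (1.0, 0.2, DependencyLabel.DEPENDENT),
            (1.0, 1.05, DependencyLabel.INDEPENDENT),
            (0.5, 1.2, DependencyLabel.INDUCED),
            (1.0, 0.5, DependencyLabel.DEPENDENT),   # boundary: AS_mut == AS_wt/theta
            (1.0, 2.0, DependencyLabel.INDUCED),     # boundary: AS_mut == AS_wt*theta
        ],
    )
    def test_threshold_rule(self, as_wt, as_mut, expected):
        assert dependency_call(as_wt, as_mut, theta=2.0).label is expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            dependency_call(1.0, 1.0, theta=1.0)
        with pytest.raises(ValueError):
            dependency_call(0.0, 1.0, theta=2.0)
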