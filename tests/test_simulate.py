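import filecmp

import numpy as np
import pytest

import chiscan as cs
from chiscan.polarity import find_occurrences
from chiscan.simulate import (
    _on_forward_leading_arc,
    make_toy_dataset,
    plant_polarized_motifs,
    simulate_genome,
    simulate_species_trio,
)


class TestSimulateGenome:
    def test_gc_within_three_binomial_se(self):
        g = simulate_genome(300_000, gc=0.6, seed=1)
        gc = cs.gc_content(g.sequence)
        se = np.sqrt(0.6 * 0.4 / 300_000)
        assert abs(gc - 0.6) < 3 * se

    @pytest.mark.parametrize("gc", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_gc_rejected(self, gc):
        with pytest.raises(ValueError):
            simulate_genome(1000, gc=gc)

    def test_determinism(self):
        a = simulate_genome(5000, gc=0.5, seed=9)
        b = simulate_genome(5000, gc=0.5, seed=9)
        assert a.sequence == b.sequence

    def test_higher_order_requires_template(self):
        with pytest.raises(ValueError, match="template"):
            simulate_genome(1000, order=2)

    def test_markov_background_from_template(self, background_200kb):
        g = simulate_genome(
            50_000, order=2, template=background_200kb[:50_000], seed=3
        )
        assert len(g) == 50_000


class TestPlantPolarizedMotifs:
    def _plant(self, pol, seed, L=200_000, density=0.2):
        g = simulate_genome(L, gc=0.5, seed=seed)
        return plant_polarized_motifs(
            g, "GCTGGTGG", density, ori=1, ter=L // 2,
            polarization_level=pol, seed=seed + 1,
        )

    def test_poisson_count_near_target(self):
        g, truth = self._plant(0.9, seed=10)
        lam = 200_000 / 1000 * 0.2  # 40
        assert abs(truth.n_planted - lam) < 4 * np.sqrt(lam)

    def test_full_polarization_geometry(self):
        g, truth = self._plant(1.0, seed=20)
        for pos, strand in truth.planted:
            on_arc1 = _on_forward_leading_arc(pos, 1, 100_000, 200_000)
            assert strand == ("+" if on_arc1 else "-")

    def test_planted_sites_recovered_by_scan(self):
        g, truth = self._plant(0.9, seed=30)
        occ = set(find_occurrences(g, "GCTGGTGG").occurrences)
        assert set(truth.planted) <= occ

    def test_polarization_fraction_calibrated(self):
        g, truth = self._plant(0.8, seed=40, L=500_000, density=0.4)
        n = truth.n_planted
        on_leading = sum(
            1
            for pos, strand in truth.planted
            if (strand == "+")
            == _on_forward_leading_arc(pos, 1, 250_000, 500_000)
        )
        se = np.sqrt(0.8 * 0.2 / n)
        assert abs(on_leading / n - 0.8) < 3 * se

    def test_density_too_high_rejected(self):
        g = simulate_genome(2000, gc=0.5, seed=5)
        with pytest.raises(ValueError):
            plant_polarized_motifs(
                g, "GCTGGTGG", 200.0, ori=1, ter=1000,
                polarization_level=0.9, seed=6,
            )

    def test_ori_equals_ter_rejected(self):
        g = simulate_genome(10_000, gc=0.5, seed=5)
        with pytest.raises(ValueError):
            plant_polarized_motifs(
                g, "GCTGGTGG", 1.0, ori=5, ter=5,
                polarization_level=0.9,
            )


class TestSimulateSpeciesTrio:
    def test_identical_neighbors_full_core(self):
        species, truth = simulate_species_trio(
            6, 300, (1.0, 1.0), seed=1
        )
        core = cs.build_pseudo_core(
            "focal",
            species["focal"].gene_seqs,
            species["focal"].proteins,
            {
                "near1": species["near1"].proteins,
                "near2": species["near2"].proteins,
            },
        )
        assert len(core) == 6

    def test_realized_identity_near_target(self):
        _, truth = simulate_species_trio(8, 900, (0.9, 0.9), seed=2)
        # mean across genes is tight; single genes carry binomial noise
        assert abs(truth.nt_identity.mean() - 0.9) < 0.02
        per_gene_sd = np.sqrt(0.9 * 0.1 / 900)
        assert (truth.nt_identity - 0.9).abs().max() < 4 * per_gene_sd

    def test_no_internal_stops(self):
        species, _ = simulate_species_trio(5, 300, (0.7, 0.7), seed=3)
        for sim in species.values():
            for prot in sim.proteins.values():
                assert "*" not in prot

    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError):
            simulate_species_trio(0, 300, (0.9, 0.9))

    def test_features_extractable(self):
        species, _ = simulate_species_trio(4, 300, (0.8, 0.8), seed=4)
        sim = species["near1"]
        extracted = cs.extract_gene_sequences([sim.genome], sim.features)
        assert extracted == sim.gene_seqs


class TestMakeToyDataset:
    CFG = {
        "n_species_planted": 1,
        "n_species_null": 1,
        "genome_length": 30_000,
        "n_core_genes": 10,
        "core_gene_length": 600,
    }

    def test_writes_all_artifacts(self, tmp_path):
        out = make_toy_dataset(self.CFG, seed=1, out_dir=tmp_path / "toy")
        assert (out / "genomes" / "planted01.fna").exists()
        assert (out / "features" / "null01.gff").exists()
        assert (out / "core" / "planted01_core.fna").exists()
        assert (out / "tree.nwk").exists()
        assert (out / "truth.tsv").exists()

    def test_regeneration_identical(self, tmp_path):
        a = make_toy_dataset(self.CFG, seed=2, out_dir=tmp_path / "a")
        b = make_toy_dataset(self.CFG, seed=2, out_dir=tmp_path / "b")
        for rel in ("genomes/planted01.fna", "truth.tsv", "tree.nwk"):
            assert filecmp.cmp(a / rel, b / rel, shallow=False)

    def test_zero_species_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            make_toy_dataset(
                {"n_species_planted": 0, "n_species_null": 0},
                seed=1,
                out_dir=tmp_path,
            )

    def test_invalid_config_key_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="invalid config"):
            make_toy_dataset({"bogus": 1}, seed=1, out_dir=tmp_path)
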