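"""Determinism, feasibility and planted structure of the generator."""

import json

import numpy as np
import pytest

from cpgnet import GeneratorParams, ParameterError, generate, write_dataset
from cpgnet.criticality import degree


class TestDeterminism:
    def test_same_seed_byte_identical(self, small_params, tmp_path):
        m1 = write_dataset(generate(small_params), tmp_path / "a")
        m2 = write_dataset(generate(small_params), tmp_path / "b")
        assert m1["files"] == m2["files"]

    def test_different_seeds_differ(self, small_params, tmp_path):
        import dataclasses

        other = dataclasses.replace(small_params, seed=small_params.seed + 1)
        m1 = write_dataset(generate(small_params), tmp_path / "a")
        m2 = write_dataset(generate(other), tmp_path / "b")
        assert m1["files"] != m2["files"]

    def test_manifest_digest_tracks_content(self, small_params, tmp_path):
        write_dataset(generate(small_params), tmp_path / "a")
        manifest = json.loads((tmp_path / "a" / "manifest.json").read_text())
        target = tmp_path / "a" / "nodes.tsv"
        target.write_text(target.read_text() + "# tweak\n")
        import hashlib

        assert (
            hashlib.sha256(target.read_bytes()).hexdigest()
            != manifest["files"]["nodes.tsv"]
        )


class TestPlantedStructure:
    def test_zero_cpg_fraction_plants_none(self):
        ds = generate(
            GeneratorParams(
                seed=3,
                n_pathways=3,
                proteins_per_pathway=36,
                n_layers=5,
                n_groups=8,
                n_tissues=4,
                planted_cpg_fraction=0.0,
            )
        )
        assert "CPG" not in set(ds.truth.group_label.values())

    def test_truth_tables_are_consistent(self, default_dataset):
        truth = default_dataset.truth
        grouped = set().union(*truth.groups.values())
        for protein, label in truth.protein_label.items():
            if label == "OTHER":
                assert protein not in grouped
            else:
                assert protein in grouped
        for tissue, essentials in truth.essential_by_tissue.items():
            assert essentials <= default_dataset.network.signaling_ids

    def test_scale_matches_study_shape(self, default_dataset):
        n = len(default_dataset.network.signaling_ids)
        assert 350 <= n <= 1050  # ~700 +/- 50%
        assert len(default_dataset.assignment.organ_systems) == 18
        unannotated = [
            p
            for p in default_dataset.network.signaling_ids
            if not default_dataset.assignment.get(p)
        ]
        assert abs(len(unannotated) / n - 0.225) < 0.05

    def test_degree_planting_across_seeds(self):
        wins = 0
        runs = 60
        for seed in range(runs):
            ds = generate(
                GeneratorParams(
                    seed=seed,
                    n_pathways=4,
                    proteins_per_pathway=50,
                    n_layers=6,
                    n_groups=20,
                    n_tissues=6,
                )
            )
            g = ds.network.graph()
            cp = [
                degree(g, p)
                for p, lab in ds.truth.protein_label.items()
                if lab == "CP" and p in g
            ]
            pp = [
                degree(g, p)
                for p, lab in ds.truth.protein_label.items()
                if lab == "PP" and p in g
            ]
            if np.mean(cp) > np.mean(pp):
                wins += 1
        assert wins >= 0.95 * runs

    def test_infeasible_params_rejected(self):
        with pytest.raises(ParameterError):
            generate(GeneratorParams(proteins_per_pathway=10, n_layers=11))
        with pytest.raises(ParameterError):
            generate(GeneratorParams(intra_edge_prob=1.5))
        with pytest.raises(ParameterError):
            # far more groups than the mediator pool can host
            generate(
                GeneratorParams(
                    n_pathways=2,
                    proteins_per_pathway=20,
                    n_layers=3,
                    n_groups=200,
                )
            )
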