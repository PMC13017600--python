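"""Kinship recursion against textbook values and a gene-dropping oracle."""

import numpy as np
import pandas as pd
import pytest

from kinmethyl import (
    PedigreeError, build_pedigree, cohort_relatedness_matrix,
    gene_drop_kinship, kinship_matrix, parental_relatedness, read_pedigree,
    relatedness_scores,
)
from kinmethyl.pedigree import write_kinship

from conftest import random_pedigree


class TestBuildPedigree:
    def test_minimal_trio_founders_first(self):
        ped = build_pedigree(
            [
                {"id": "kid", "sire": "pa", "dam": "ma", "sex": "F"},
                {"id": "pa", "sire": "0", "dam": "NA", "sex": "M"},
                {"id": "ma", "sire": "", "dam": "0", "sex": "F"},
            ]
        )
        assert len(ped) == 3
        assert ped.ids[-1] == "kid"  # topological: parents precede offspring

    def test_self_parent_is_cycle_error(self):
        with pytest.raises(PedigreeError, match="cycle"):
            build_pedigree(
                [{"id": "X", "sire": "X", "dam": "0", "sex": "M"}]
            )

    def test_duplicate_id_error(self):
        with pytest.raises(PedigreeError, match="duplicated"):
            build_pedigree(
                [
                    {"id": "A", "sire": "0", "dam": "0", "sex": "M"},
                    {"id": "A", "sire": "0", "dam": "0", "sex": "F"},
                ]
            )

    def test_unknown_parent_reference_error(self):
        with pytest.raises(PedigreeError, match="not in the pedigree"):
            build_pedigree(
                [{"id": "A", "sire": "ghost", "dam": "0", "sex": "M"}]
            )

    def test_parent_sex_conflict_error(self):
        with pytest.raises(PedigreeError, match="sex"):
            build_pedigree(
                [
                    {"id": "A", "sire": "0", "dam": "0", "sex": "F"},
                    {"id": "B", "sire": "A", "dam": "0", "sex": "M"},
                ]
            )

    def test_half_founder_flagged(self):
        ped = build_pedigree(
            [
                {"id": "A", "sire": "0", "dam": "0", "sex": "M"},
                {"id": "B", "sire": "A", "dam": "0", "sex": "F"},
            ]
        )
        row = ped.table.set_index("id").loc["B"]
        assert bool(row["half_founder"])

    def test_generator_colony_is_topologically_ordered(self, default_dataset):
        ped, _ = default_dataset
        pos = {i: k for k, i in enumerate(ped.ids)}
        for _, row in ped.table.iterrows():
            for parent in (row["sire"], row["dam"]):
                if parent is not None:
                    assert pos[parent] < pos[row["id"]]


class TestKinshipMatrix:
    def test_textbook_values(self, trio_pedigree):
        kin = kinship_matrix(trio_pedigree)
        assert kin["A", "B"] == 0.0          # founders unrelated
        assert kin["A", "A"] == 0.5          # non-inbred self-kinship
        assert kin["A", "C"] == 0.25         # parent-offspring
        assert kin["C", "D"] == 0.25         # full sibs
        assert kin["E", "E"] == 0.625        # full-sib mating: 0.5*(1+0.25)

    def test_half_sibs(self):
        ped = build_pedigree(
            [
                {"id": "S", "sire": "0", "dam": "0", "sex": "M"},
                {"id": "D1", "sire": "0", "dam": "0", "sex": "F"},
                {"id": "D2", "sire": "0", "dam": "0", "sex": "F"},
                {"id": "H1", "sire": "S", "dam": "D1", "sex": "M"},
                {"id": "H2", "sire": "S", "dam": "D2", "sex": "F"},
            ]
        )
        assert kinship_matrix(ped)["H1", "H2"] == 0.125

    def test_gene_dropping_oracle_random_pedigrees(self):
        """Recursion agrees with Monte-Carlo IBD estimates: across many
        pairs ~99.7% of deviations fall within 3 MC standard errors, and
        none exceeds what pure sampling noise allows."""
        rng = np.random.default_rng(2024)
        zs = []
        for rep in range(8):
            ped = build_pedigree(
                random_pedigree(rng, int(rng.integers(8, 16)))
            )
            kin = kinship_matrix(ped)
            mc = gene_drop_kinship(ped, n_reps=20_000, seed=rep)
            pos = {i: k for k, i in enumerate(kin.ids)}
            for _, row in mc.iterrows():
                exact = kin.phi[pos[row["id1"]], pos[row["id2"]]]
                if row["se"] == 0:
                    assert row["phi_hat"] == exact
                else:
                    zs.append(abs(row["phi_hat"] - exact) / row["se"])
        zs = np.asarray(zs)
        assert (zs <= 3.0).mean() >= 0.99
        assert zs.max() <= 5.0

    def test_adding_individual_preserves_existing_phi(self, trio_pedigree):
        kin_before = kinship_matrix(trio_pedigree)
        extended = pd.concat(
            [
                trio_pedigree.table[["id", "sire", "dam", "sex"]],
                pd.DataFrame(
                    [{"id": "F", "sire": "C", "dam": "B", "sex": "F"}]
                ),
            ]
        )
        kin_after = kinship_matrix(build_pedigree(extended))
        for i in trio_pedigree.ids:
            for j in trio_pedigree.ids:
                assert kin_after[i, j] == kin_before[i, j]

    def test_phi_bounded_by_half_without_inbreeding(self):
        rng = np.random.default_rng(7)
        for rep in range(5):
            ped = build_pedigree(random_pedigree(rng, 20))
            kin = kinship_matrix(ped)
            inbred = kin.inbreeding() > 0
            off = kin.phi - np.diag(np.diag(kin.phi))
            for a in range(len(ped)):
                for b in range(a):
                    if not (inbred.iloc[a] or inbred.iloc[b]):
                        assert off[a, b] <= 0.5 + 1e-12
            # off-diagonal <= min of the two self-kinships
            diag = np.diag(kin.phi)
            assert np.all(
                off <= np.minimum.outer(diag, diag) + 1e-12
            )


class TestParentalRelatedness:
    def test_offspring_of_unrelated_founders_scores_zero(self, trio_pedigree):
        assert parental_relatedness(trio_pedigree, "C") == 0.0

    def test_offspring_of_full_sibs_scores_fifty_percent(self, trio_pedigree):
        assert parental_relatedness(trio_pedigree, "E") == pytest.approx(50.0)
        assert parental_relatedness(trio_pedigree, "E", scale="phi") == (
            pytest.approx(0.25)
        )
        assert parental_relatedness(trio_pedigree, "E", scale="2phi") == (
            pytest.approx(0.5)
        )

    def test_founder_score_is_missing(self, trio_pedigree):
        assert np.isnan(parental_relatedness(trio_pedigree, "A"))

    def test_unknown_scale_rejected(self, trio_pedigree):
        with pytest.raises(ValueError):
            parental_relatedness(trio_pedigree, "E", scale="bogus")

    def test_scores_series_alignment(self, trio_pedigree):
        scores = relatedness_scores(trio_pedigree)
        assert list(scores.index) == trio_pedigree.ids
        assert np.isnan(scores["A"]) and scores["E"] == pytest.approx(50.0)


class TestCohortMatrix:
    def test_unrelated_cohort_all_zero(self):
        ped = build_pedigree(
            [{"id": f"F{k}", "sire": "0", "dam": "0",
              "sex": "M" if k % 2 else "F"} for k in range(6)]
        )
        matrix, summary = cohort_relatedness_matrix(
            ped, ped.ids, n_permutations=50
        )
        off = matrix.to_numpy() - np.diag(np.diag(matrix.to_numpy()))
        assert np.all(off == 0)
        assert summary["correlation"] == 0.0

    def test_single_animal_cohort(self, trio_pedigree):
        matrix, _ = cohort_relatedness_matrix(trio_pedigree, ["E"])
        assert matrix.shape == (1, 1)
        assert matrix.iloc[0, 0] == 0.625

    def test_empty_cohort_error(self, trio_pedigree):
        with pytest.raises(ValueError):
            cohort_relatedness_matrix(trio_pedigree, [])

    def test_rows_ordered_by_ascending_relatedness(self, default_dataset):
        ped, ds = default_dataset
        cohort = list(ds.metadata.index)[:40]
        matrix, _ = cohort_relatedness_matrix(
            ped, cohort, n_permutations=10
        )
        scores = relatedness_scores(ped, list(matrix.index))
        vals = scores.to_numpy()
        assert np.all(np.diff(vals[~np.isnan(vals)]) >= 0)


def test_pedigree_tsv_round_trip(tmp_path, trio_pedigree):
    path = tmp_path / "ped.tsv"
    trio_pedigree.table[["id", "sire", "dam", "sex"]].fillna("0").to_csv(
        path, sep="\t", index=False
    )
    again = read_pedigree(path)
    assert again.ids == trio_pedigree.ids
    out = tmp_path / "phi.tsv"
    write_kinship(kinship_matrix(again), out)
    loaded = pd.read_csv(out, sep="\t", index_col=0)
    assert loaded.loc["E", "E"] == pytest.approx(0.625)
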