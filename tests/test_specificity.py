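"""Specificity classes, implication mining, determinants, minimal sets."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hetsel.specificity import (
    IncompatibilityMatrix,
    determinant_positions,
    implication_rules,
    minimal_discriminating_set,
    partition_classes,
)


def _random_matrix(seed, n_alleles=8, n_testers=4):
    rng = np.random.default_rng(seed)
    data = pd.DataFrame(
        rng.integers(0, 2, size=(n_alleles, n_testers)),
        index=[f"a{i}" for i in range(n_alleles)],
        columns=[f"t{j}" for j in range(n_testers)],
    )
    return IncompatibilityMatrix(data=data)


class TestPartition:
    def test_hetc_matrix_gives_seven_documented_classes(self, hetc_matrix):
        classes = partition_classes(hetc_matrix)
        assert len(classes) == 7
        groups = classes.as_dict()
        assert groups["het-c1"] == ["het-c1", "het-c5"]
        assert groups["het-c3"] == ["het-c3", "het-c6"]
        assert groups["het-c4"] == ["het-c4", "het-c10", "het-c11"]
        for singleton in ("het-c2", "het-c7", "het-c8", "het-c9"):
            assert groups[singleton] == [singleton]

    def test_identical_rows_collapse_to_one_class(self):
        m = IncompatibilityMatrix(
            data=pd.DataFrame(
                [[1, 0], [1, 0], [1, 0]], index=list("abc"), columns=["t1", "t2"]
            )
        )
        assert len(partition_classes(m)) == 1

    @given(st.integers(0, 5000))
    def test_class_count_equals_distinct_rows(self, seed):
        m = _random_matrix(seed)
        expected = len({tuple(r) for r in m.data.to_numpy()})
        assert len(partition_classes(m)) == expected

    @given(st.integers(0, 2000))
    def test_invariant_under_row_and_column_permutation(self, seed):
        m = _random_matrix(seed)
        rng = np.random.default_rng(seed + 1)
        permuted = IncompatibilityMatrix(
            data=m.data.iloc[
                rng.permutation(len(m.alleles)), rng.permutation(len(m.testers))
            ]
        )
        a = {frozenset(c) for c in partition_classes(m).classes}
        b = {frozenset(c) for c in partition_classes(permuted).classes}
        assert a == b


class TestImplications:
    def test_hetc_hierarchy_is_mined_strictly(self, hetc_matrix):
        strict = {
            (r.antecedent, r.consequent)
            for r in implication_rules(hetc_matrix)
            if r.strict
        }
        assert ("het-e1", "het-d1") in strict
        assert ("het-e3", "het-e2") in strict
        assert ("het-d2", "het-d1") in strict
        # the converses do not hold
        assert ("het-d1", "het-e1") not in strict
        assert ("het-e2", "het-e3") not in strict

    def test_all_zero_matrix_yields_no_rules(self):
        m = IncompatibilityMatrix(
            data=pd.DataFrame(0, index=list("ab"), columns=["t1", "t2"])
        )
        assert implication_rules(m) == []

    @given(st.integers(0, 5000))
    def test_agrees_with_brute_force_pair_enumeration(self, seed):
        m = _random_matrix(seed)
        mined = {
            (r.antecedent, r.consequent): set(r.exceptions)
            for r in implication_rules(m, max_exceptions=2)
        }
        for a, b in itertools.permutations(m.testers, 2):
            with_a = [al for al in m.alleles if m.data.at[al, a] == 1]
            exceptions = {al for al in with_a if m.data.at[al, b] == 0}
            support = len(with_a) - len(exceptions)
            expected = bool(with_a) and len(exceptions) <= 2 and support >= 1
            assert ((a, b) in mined) == expected
            if expected:
                assert mined[(a, b)] == exceptions


def _toy_protein_table(profiles):
    positions = sorted(next(iter(profiles.values())).keys())
    return pd.DataFrame(
        {
            "position": positions,
            "residues": [
                "".join(sorted({p[pos] for p in profiles.values()}))
                for pos in positions
            ],
            **{a: [p[pos] for pos in positions] for a, p in profiles.items()},
        }
    )


class TestMinimalSet:
    def test_hetc_minimal_set_is_the_seven_positions(
        self, hetc_protein_table, hetc_classes
    ):
        assert minimal_discriminating_set(hetc_protein_table, hetc_classes) == [
            17, 65, 84, 118, 126, 133, 153,
        ]

    def test_single_class_needs_no_positions(self, hetc_protein_table, hetc_matrix):
        all_same = IncompatibilityMatrix(
            data=pd.DataFrame(
                1, index=list(hetc_matrix.alleles), columns=["t1"]
            )
        )
        classes = partition_classes(all_same)
        assert minimal_discriminating_set(hetc_protein_table, classes) == []

    def test_solution_separates_and_is_minimal(self, hetc_protein_table, hetc_classes):
        """Post-hoc witnesses: the set separates every class pair, and
        dropping any one position breaks separation."""
        solution = minimal_discriminating_set(hetc_protein_table, hetc_classes)
        prof = {
            a: {int(p): hetc_protein_table[a][i]
                for i, p in enumerate(hetc_protein_table["position"])}
            for a in hetc_classes.alleles
        }

        def separates(positions):
            for ca, cb in itertools.combinations(range(len(hetc_classes)), 2):
                for a in hetc_classes.classes[ca]:
                    for b in hetc_classes.classes[cb]:
                        if all(prof[a][p] == prof[b][p] for p in positions):
                            return False
            return True

        assert separates(solution)
        for drop in solution:
            assert not separates([p for p in solution if p != drop])

    @given(st.integers(0, 3000))
    def test_matches_power_set_oracle_on_toys(self, seed):
        rng = np.random.default_rng(seed)
        positions = [1, 2, 3, 4, 5]
        profiles = {
            f"a{i}": {p: "XY"[rng.integers(0, 2)] for p in positions}
            for i in range(4)
        }
        table = _toy_protein_table(profiles)
        m = IncompatibilityMatrix(
            data=pd.DataFrame(
                rng.integers(0, 2, size=(4, 3)),
                index=[f"a{i}" for i in range(4)],
                columns=["t1", "t2", "t3"],
            )
        )
        classes = partition_classes(m)

        def separates(subset):
            for ca, cb in itertools.combinations(range(len(classes)), 2):
                for a in classes.classes[ca]:
                    for b in classes.classes[cb]:
                        if all(profiles[a][p] == profiles[b][p] for p in subset):
                            return False
            return True

        oracle = None
        for k in range(len(positions) + 1):
            feasible = sorted(
                sorted(c) for c in itertools.combinations(positions, k)
                if separates(c)
            )
            if feasible:
                oracle = feasible[0]
                break

        if oracle is None:
            with pytest.raises(ValueError, match="identical residue profiles"):
                minimal_discriminating_set(table, classes)
        else:
            assert minimal_discriminating_set(table, classes) == oracle


class TestDeterminants:
    def test_hetc_causal_positions(self, hetc_protein_table, hetc_classes):
        records = determinant_positions(hetc_protein_table, hetc_classes)
        causal = {(r.position, frozenset((r.allele_a, r.allele_b)))
                  for r in records if r.causal}
        # single Cys->Arg exchange switching the class of het-c8
        assert (118, frozenset(("het-c1", "het-c8"))) in causal
        # position 133 separates het-c1/het-c5 from het-c3
        assert (133, frozenset(("het-c1", "het-c3"))) in causal
        assert (133, frozenset(("het-c5", "het-c3"))) in causal
        # the same-class pair het-c1/het-c5 also differs only at 133: not causal
        non_causal = {(r.position, frozenset((r.allele_a, r.allele_b)))
                      for r in records if not r.causal}
        assert (133, frozenset(("het-c1", "het-c5"))) in non_causal

    def test_identical_proteins_give_no_records(self, hetc_matrix):
        classes = partition_classes(hetc_matrix)
        table = _toy_protein_table(
            {a: {1: "A", 2: "C"} for a in hetc_matrix.alleles}
        )
        table["residues"] = ["A", "C"]
        assert determinant_positions(table, classes) == []

    @given(st.integers(0, 3000))
    def test_agrees_with_pairwise_hamming_oracle(self, seed):
        rng = np.random.default_rng(seed)
        positions = [1, 2, 3, 4]
        profiles = {
            f"a{i}": {p: "XY"[rng.integers(0, 2)] for p in positions}
            for i in range(5)
        }
        table = _toy_protein_table(profiles)
        m = _random_matrix(seed + 7, n_alleles=5, n_testers=3)
        m = IncompatibilityMatrix(
            data=m.data.set_axis([f"a{i}" for i in range(5)], axis=0)
        )
        classes = partition_classes(m)
        got = {
            (r.position, frozenset((r.allele_a, r.allele_b)))
            for r in determinant_positions(table, classes)
        }
        expected = set()
        for a, b in itertools.combinations(profiles, 2):
            diffs = [p for p in positions if profiles[a][p] != profiles[b][p]]
            if len(diffs) == 1:
                expected.add((diffs[0], frozenset((a, b))))
        assert got == expected
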