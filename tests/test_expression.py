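import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nestedgenes.expression import (
    TISSUES,
    ExpressionTable,
    compute_tau,
    derived_vs_ancestral_divergence,
    divergence_distributions,
    expression_divergence,
    filter_expressed,
    profile_table,
    tissue_profile,
)
from nestedgenes.nesting import NestedPair, NestingCatalog
from nestedgenes.phylo_events import NestingEventCall
from nestedgenes.synthetic import SimulationConfig, simulate_expression


def make_table(rows, species="t"):
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(TISSUES))
    return ExpressionTable(species=species, values=df.astype(float))


class TestFilterExpressed:
    def test_threshold_is_inclusive(self):
        table = make_table({
            "low": [0.2, 0.1, 0, 0, 0, 0, 0.9],
            "boundary": [1.0, 0, 0, 0, 0, 0, 0],
            "high": [0.5, 0, 7.2, 0, 0, 0, 0],
        })
        kept = filter_expressed(table)
        assert set(kept.values.index) == {"boundary", "high"}

    def test_custom_threshold(self):
        table = make_table({"a": [0.5, 0, 0, 0, 0, 0, 0]})
        assert len(filter_expressed(table, threshold=0.5)) == 1
        assert len(filter_expressed(table, threshold=0.6)) == 0


class TestTau:
    @pytest.mark.parametrize(
        "tpm, expected",
        [
            ([5, 5, 5, 5, 5, 5, 5], 0.0),
            ([10, 0, 0, 0, 0, 0, 0], 1.0),
            ([8, 2, 2, 2, 2, 2, 2], 0.75),
        ],
    )
    def test_closed_forms(self, tpm, expected):
        assert compute_tau(tpm) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_vector_undefined(self):
        with pytest.raises(ValueError, match="all-zero"):
            compute_tau([0] * 7)

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.floats(min_value=0, max_value=1e6), min_size=7, max_size=7)
        .filter(lambda x: max(x) > 0),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_scale_invariance_and_range(self, tpm, c):
        tau = compute_tau(tpm)
        assert 0 <= tau <= 1
        assert compute_tau([c * x for x in tpm]) == pytest.approx(tau, abs=1e-9)


class TestTissueProfile:
    def test_relative_profile_sums_to_one(self):
        table = make_table({"g": [8, 2, 2, 2, 2, 2, 2]})
        prof = tissue_profile(table, "g")
        assert sum(prof.relative) == pytest.approx(1.0)
        assert prof.primary_tissue == "brain"
        assert prof.tau == pytest.approx(0.75)
        assert not prof.is_specific

    def test_specificity_flag_matches_strict_cutoff(self):
        table = make_table({
            "spec": [100, 0.5, 0, 0, 0, 0, 0],
            "broad": [5, 4, 5, 5, 4, 5, 5],
        })
        df = profile_table(table).set_index("gene_id")
        assert bool(df.loc["spec"].is_specific) and df.loc["spec"].tau > 0.9
        assert not df.loc["broad"].is_specific
        # flag is exactly the strict inequality
        assert all(df.is_specific == (df.tau > 0.9))

    def test_tau_one_implies_single_nonzero_tissue(self):
        table = make_table({"g": [0, 0, 0, 0, 0, 0, 42]})
        prof = tissue_profile(table, "g")
        assert prof.tau == 1.0
        assert sum(r > 0 for r in prof.relative) == 1
        assert prof.primary_tissue == "testis"

    def test_tie_broken_by_canonical_order(self):
        table = make_table({"g": [3, 3, 1, 1, 1, 1, 1]})
        assert tissue_profile(table, "g").primary_tissue == "brain"


class TestDivergence:
    def test_identical_profiles_have_zero_distance(self):
        table = make_table({"a": [1, 2, 3, 4, 5, 6, 7], "b": [2, 4, 6, 8, 10, 12, 14]})
        d = expression_divergence(tissue_profile(table, "a"), tissue_profile(table, "b"))
        assert d.distance == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_single_tissue_profiles_attain_sqrt2(self):
        table = make_table({"a": [9, 0, 0, 0, 0, 0, 0], "b": [0, 3, 0, 0, 0, 0, 0]})
        d = expression_divergence(tissue_profile(table, "a"), tissue_profile(table, "b"))
        assert d.distance == pytest.approx(math.sqrt(2))

    def test_half_overlapping_profiles(self):
        table = make_table({"a": [1, 1, 0, 0, 0, 0, 0], "b": [1, 0, 1, 0, 0, 0, 0]})
        d = expression_divergence(tissue_profile(table, "a"), tissue_profile(table, "b"))
        assert d.distance == pytest.approx(math.sqrt(0.5))

    def test_mismatched_tissue_lists_rejected(self):
        table = make_table({"a": [1, 0, 0, 0, 0, 0, 0]})
        other = ExpressionTable(
            species="x",
            values=pd.DataFrame([[1.0] * 7], index=["b"], columns=list(TISSUES)),
            tissues=tuple(reversed(TISSUES)),
        )
        with pytest.raises(ValueError, match="tissue lists differ"):
            expression_divergence(tissue_profile(table, "a"), tissue_profile(other, "b"))

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_metric_properties_on_random_triples(self, data):
        vecs = [
            data.draw(
                st.lists(st.floats(min_value=0, max_value=100), min_size=7, max_size=7)
                .filter(lambda x: sum(x) > 1e-6)
            )
            for _ in range(3)
        ]
        table = make_table({f"g{i}": v for i, v in enumerate(vecs)})
        p = [tissue_profile(table, f"g{i}") for i in range(3)]
        d01 = expression_divergence(p[0], p[1]).distance
        d10 = expression_divergence(p[1], p[0]).distance
        d02 = expression_divergence(p[0], p[2]).distance
        d12 = expression_divergence(p[1], p[2]).distance
        assert 0 <= d01 <= math.sqrt(2) + 1e-9
        assert d01 == pytest.approx(d10)
        assert d02 <= d01 + d12 + 1e-9  # triangle inequality


def catalog_with(pairs, unnested):
    cat = NestingCatalog(species="t")
    for e, i in pairs:
        cat.pairs.append(NestedPair(e, i, None, "opposite", True))
    for g, chrom in unnested.items():
        cat.unnested_ids.add(g)
        cat.unnested_chrom[g] = chrom
    return cat


class TestDivergenceDistributions:
    def test_single_chromosome_universe_enumerates_intra_only(self):
        rng = np.random.default_rng(0)
        table = make_table({g: rng.uniform(1, 10, 7) for g in ("u1", "u2", "u3")})
        cat = catalog_with([], {"u1": "chr1", "u2": "chr1", "u3": "chr1"})
        with pytest.warns(UserWarning, match="subsample exceeds universe"):
            dists = divergence_distributions(cat, table, subsample=100, seed=0)
        assert len(dists["intra"]) == 3 and len(dists["inter"]) == 0

    def test_both_expressed_rule_for_nested_pairs(self):
        table = make_table({"E1": [5, 1, 1, 1, 1, 1, 1], "I1": [0, 9, 0, 0, 0, 0, 0]})
        cat = catalog_with([("E1", "I1"), ("E2", "I2")], {})
        dists = divergence_distributions(cat, table, subsample=10, seed=0)
        # only the pair with both members in the table is measured
        assert [(d.gene_a, d.gene_b) for d in dists["nested"]] == [("E1", "I1")]

    def test_null_simulation_nested_matches_inter(self):
        """Independent profiles for nested genes: the no-interference null
        predicts nested and inter-chromosomal divergence agree."""
        config = SimulationConfig(seed=3, specificity_fraction=0.3)
        genes = [f"E{i}" for i in range(120)] + [f"I{i}" for i in range(120)] + \
            [f"U{i}" for i in range(200)]
        table = simulate_expression(config, genes)
        pairs = [(f"E{i}", f"I{i}") for i in range(120)]
        unnested = {f"U{i}": f"chr{i % 5}" for i in range(200)}
        dists = divergence_distributions(
            catalog_with(pairs, unnested), table, subsample=2000, seed=3
        )
        mean_nested = np.mean([d.distance for d in dists["nested"]])
        mean_inter = np.mean([d.distance for d in dists["inter"]])
        assert mean_nested == pytest.approx(mean_inter, abs=0.08)

    def test_interference_simulation_separates_nested_pairs(self):
        """Forcing nested pairs into disjoint primary tissues raises their
        divergence above the inter-chromosomal background."""
        config = SimulationConfig(seed=4, specificity_fraction=0.3)
        pairs = [(f"E{i}", f"I{i}") for i in range(120)]
        genes = [g for p in pairs for g in p] + [f"U{i}" for i in range(200)]
        table = simulate_expression(config, genes, disjoint_pairs=pairs)
        unnested = {f"U{i}": f"chr{i % 5}" for i in range(200)}
        dists = divergence_distributions(
            catalog_with(pairs, unnested), table, subsample=2000, seed=4
        )
        mean_nested = np.mean([d.distance for d in dists["nested"]])
        mean_inter = np.mean([d.distance for d in dists["inter"]])
        assert mean_nested > mean_inter + 0.1


class TestDerivedVsAncestral:
    @staticmethod
    def call(cls="human_nesting"):
        return NestingEventCall(
            external_orthogroup={"human": "hE", "mouse": "mE"},
            internal_orthogroup={"human": "hI", "mouse": "mI"},
            call=cls,
            evidence="",
        )

    def test_identical_relative_profiles_give_zero(self):
        human = make_table({"hE": [2, 2, 2, 2, 2, 2, 2], "hI": [7, 0, 0, 0, 0, 0, 0]}, "human")
        mouse = make_table({"mE": [9, 9, 9, 9, 9, 9, 9], "mI": [3, 0, 0, 0, 0, 0, 0]}, "mouse")
        out = derived_vs_ancestral_divergence([self.call()], {"human": human, "mouse": mouse})
        assert len(out) == 2
        assert all(d.distance == pytest.approx(0, abs=1e-12) for d in out)

    def test_empty_call_list_gives_empty_result(self):
        assert derived_vs_ancestral_divergence([], {}) == []

    def test_non_nesting_calls_ignored(self):
        out = derived_vs_ancestral_divergence(
            [self.call("pre_divergence"), self.call("unresolved")], {}
        )
        assert out == []

    def test_missing_expression_skipped(self):
        human = make_table({"hE": [2, 2, 2, 2, 2, 2, 2]}, "human")
        mouse = make_table({"mE": [9, 9, 9, 9, 9, 9, 9]}, "mouse")
        out = derived_vs_ancestral_divergence([self.call()], {"human": human, "mouse": mouse})
        assert len(out) == 1  # internal pair skipped, external measured

    def test_injected_divergence_exceeds_control(self):
        """Shifting the derived copies' profiles after nesting must raise
        the cross-species distance above the no-injection control."""
        rng = np.random.default_rng(9)
        base = {f"g{i}": rng.dirichlet(np.ones(7)) * 50 for i in range(20)}
        human = make_table({f"h_{g}": v for g, v in base.items()}, "human")
        mouse_same = make_table({f"m_{g}": v for g, v in base.items()}, "mouse")
        shifted = {g: np.roll(v, 2) for g, v in base.items()}
        mouse_shift = make_table({f"m_{g}": v for g, v in shifted.items()}, "mouse")
        calls = [
            NestingEventCall(
                external_orthogroup={"human": f"h_g{i}", "mouse": f"m_g{i}"},
                internal_orthogroup={"human": f"h_g{i+10}", "mouse": f"m_g{i+10}"},
                call="human_nesting",
                evidence="",
            )
            for i in range(10)
        ]
        control = derived_vs_ancestral_divergence(calls, {"human": human, "mouse": mouse_same})
        injected = derived_vs_ancestral_divergence(calls, {"human": human, "mouse": mouse_shift})
        assert np.mean([d.distance for d in injected]) > np.mean(
            [d.distance for d in control]
        )


class TestTableIO:
    def test_tsv_round_trip_case_insensitive_tissues(self, tmp_path):
        path = tmp_path / "tpm.tsv"
        path.write_text(
            "gene_id\tBrain\tLung\tLiver\tSpleen\tKidney\tColon\tTestis\n"
            "g1\t1\t2\t3\t4\t5\t6\t7\n"
        )
        table = ExpressionTable.from_tsv(path, "t")
        assert list(table.values.columns) == list(TISSUES)
        assert table.values.loc["g1", "testis"] == 7

    def test_missing_tissue_column_rejected(self, tmp_path):
        path = tmp_path / "tpm.tsv"
        path.write_text("gene_id\tbrain\tlung\ng1\t1\t2\n")
        with pytest.raises(ValueError, match="missing tissue"):
            ExpressionTable.from_tsv(path, "t")

    def test_negative_tpm_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            make_table({"g": [-1, 0, 0, 0, 0, 0, 0]})
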