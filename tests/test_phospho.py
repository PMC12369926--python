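"""Phosphosite evidence filtering and splicing-machinery cross-reference."""

import numpy as np
import pandas as pd
import pytest

from isoswitch.phospho import (crossref_splicing, evidence_filter,
                               parse_mod_rsd, residue_percentages,
                               split_by_residue, subclass_proportions)
from isoswitch.simulate import simulate_phospho_tables

from _oracles import naive_crossref, naive_evidence_pass


def phospho_frame(rows):
    return pd.DataFrame(rows, columns=["protein", "residue", "position",
                                       "LT_LIT", "MS_LIT", "MS_CST"])


def random_phospho(rng, n=1000):
    return phospho_frame({
        "protein": [f"P{i}" for i in rng.integers(0, 200, size=n)],
        "residue": rng.choice(["S", "T", "Y"], size=n),
        "position": rng.integers(1, 500, size=n),
        "LT_LIT": rng.poisson(0.5, size=n),
        "MS_LIT": rng.poisson(1.2, size=n),
        "MS_CST": rng.poisson(1.2, size=n),
    })


class TestEvidenceFilter:
    @pytest.mark.parametrize("lt,ms_lit,ms_cst,kept", [
        (1, 0, 0, True),    # a single low-throughput report suffices
        (0, 2, 0, False),   # two high-throughput reports are not enough
        (0, 2, 1, True),    # summed high-throughput reports reach three
        (0, 0, 3, True),
        (0, 0, 0, False),
    ])
    def test_rule(self, lt, ms_lit, ms_cst, kept):
        df = phospho_frame([("P1", "Y", 10, lt, ms_lit, ms_cst)])
        assert (len(evidence_filter(df)) == 1) == kept

    def test_either_column_rule(self):
        df = phospho_frame([("P1", "Y", 10, 0, 2, 1)])
        assert len(evidence_filter(df, ms_rule="either")) == 0
        df2 = phospho_frame([("P1", "Y", 10, 0, 3, 0)])
        assert len(evidence_filter(df2, ms_rule="either")) == 1

    def test_monotone_in_evidence(self, rng):
        df = random_phospho(rng, 300)
        kept = set(evidence_filter(df).index)
        boosted = df.copy()
        boosted["MS_LIT"] += 1
        assert kept <= set(evidence_filter(boosted).index)

    def test_matches_row_scan_oracle(self, rng):
        df = random_phospho(rng, 1000)
        kept = evidence_filter(df)
        expected = naive_evidence_pass(df.to_dict("records"))
        assert len(kept) == len(expected)
        assert kept.reset_index(drop=True).equals(
            pd.DataFrame(expected)[kept.columns].reset_index(drop=True))


class TestResidueSplit:
    def test_partition_sizes(self):
        df = phospho_frame(
            [("P", "S", i, 1, 0, 0) for i in range(10)]
            + [("P", "T", i, 1, 0, 0) for i in range(5)]
            + [("P", "Y", i, 1, 0, 0) for i in range(3)]
        )
        sets, rejected = split_by_residue(df)
        assert [len(sets[r]) for r in "STY"] == [10, 5, 3]
        assert rejected == 0

    def test_empty_input(self):
        sets, rejected = split_by_residue(phospho_frame([]))
        assert all(len(s) == 0 for s in sets.values())

    def test_unknown_residue_counted(self):
        df = phospho_frame([("P", "H", 1, 1, 0, 0), ("P", "Y", 2, 1, 0, 0)])
        sets, rejected = split_by_residue(df)
        assert rejected == 1 and len(sets["Y"]) == 1

    def test_percentages_sum_to_100(self, rng):
        pct = residue_percentages(random_phospho(rng, 500))
        assert pct.sum() == pytest.approx(100.0)

    def test_mod_rsd_parsing(self):
        assert parse_mod_rsd("Y416") == ("Y", 416)
        assert parse_mod_rsd("S12-p") == ("S", 12)
        with pytest.raises(ValueError):
            parse_mod_rsd("K48")


class TestCrossref:
    def _tables(self, rng, n=1000):
        phospho = random_phospho(rng, n)
        catalogue = pd.DataFrame({
            "protein": [f"P{i}" for i in range(0, 200, 2)],
            "subclass": rng.choice(["hnRNP", "SR protein", "core snRNP"],
                                   size=100),
            "direct": True,
        })
        y_sites = phospho[phospho["residue"] == "Y"]
        picked = y_sites.sample(n=min(30, len(y_sites)), random_state=3)
        kinase = pd.DataFrame({
            "kinase": "SRC",
            "substrate": picked["protein"].to_numpy(),
            "residue": "Y",
            "position": picked["position"].to_numpy(),
        })
        return phospho, catalogue, kinase

    def test_off_catalogue_sites_excluded(self):
        phospho = phospho_frame([("NOPE", "Y", 5, 1, 0, 0)])
        catalogue = pd.DataFrame({"protein": ["P1"], "subclass": ["hnRNP"],
                                  "direct": [True]})
        kinase = pd.DataFrame(columns=["kinase", "substrate", "residue", "position"])
        assert len(crossref_splicing(phospho, catalogue, kinase)) == 0

    def test_exact_position_match_flags_src(self):
        phospho = phospho_frame([("P1", "Y", 5, 1, 0, 0), ("P1", "Y", 9, 1, 0, 0)])
        catalogue = pd.DataFrame({"protein": ["P1"], "subclass": ["hnRNP"],
                                  "direct": [True]})
        kinase = pd.DataFrame({"kinase": ["SRC"], "substrate": ["P1"],
                               "residue": ["Y"], "position": [5]})
        out = crossref_splicing(phospho, catalogue, kinase)
        flags = dict(zip(out["position"], out["src_substrate"]))
        assert flags == {5: True, 9: False}

    def test_matches_brute_force_join(self, rng):
        phospho, catalogue, kinase = self._tables(rng)
        out = crossref_splicing(phospho, catalogue, kinase)
        expected = naive_crossref(phospho.to_dict("records"),
                                  catalogue.to_dict("records"),
                                  kinase.to_dict("records"))
        assert len(out) == len(expected)
        got = set(zip(out["protein"], out["position"], out["src_substrate"]))
        want = {(r["protein"], r["position"], r["src_substrate"]) for r in expected}
        assert got == want


class TestSubclassProportions:
    def test_single_subclass_is_100_percent(self):
        annotated = pd.DataFrame({
            "protein": ["P1", "P2"], "subclass": ["hnRNP", "hnRNP"],
            "src_substrate": [True, False],
        })
        catalogue = pd.DataFrame({"protein": ["P1", "P2"],
                                  "subclass": ["hnRNP", "hnRNP"],
                                  "direct": [True, True]})
        props = subclass_proportions(annotated, catalogue)
        assert props.loc["hnRNP", "all_y_sites"] == pytest.approx(100.0)

    def test_even_split(self):
        annotated = pd.DataFrame({
            "protein": ["P1", "P2"], "subclass": ["hnRNP", "SR protein"],
            "src_substrate": [False, False],
        })
        catalogue = pd.DataFrame({"protein": ["P1", "P2"],
                                  "subclass": ["hnRNP", "SR protein"],
                                  "direct": [True, True]})
        props = subclass_proportions(annotated, catalogue)
        assert props.loc["hnRNP", "all_y_sites"] == pytest.approx(50.0)

    def test_columns_sum_to_100_and_match_tally(self, rng):
        phospho, catalogue, kinase = TestCrossref()._tables(rng)
        annotated = crossref_splicing(phospho, catalogue, kinase)
        props = subclass_proportions(annotated, catalogue)
        for col in props.columns:
            total = props[col].sum()
            if total:
                assert total == pytest.approx(100.0, abs=1e-9)
        tally = annotated["subclass"].value_counts()
        for sub, count in tally.items():
            assert props.loc[sub, "all_y_sites"] == \
                pytest.approx(100.0 * count / len(annotated))

    def test_empty_dataset_gives_zero_column(self):
        annotated = pd.DataFrame(columns=["protein", "subclass", "src_substrate"])
        catalogue = pd.DataFrame({"protein": ["P1"], "subclass": ["hnRNP"],
                                  "direct": [True]})
        props = subclass_proportions(annotated, catalogue)
        assert (props["all_y_sites"] == 0).all()


class TestMockTables:
    def test_generator_truth_matches_module_filter(self):
        phospho, kinase, catalogue, truth = simulate_phospho_tables(3)
        kept = evidence_filter(phospho)
        assert len(kept) == truth["pass_total"]
        sets, _ = split_by_residue(kept)
        for residue in "STY":
            assert len(sets[residue]) == truth["pass_by_residue"][residue]
        annotated = crossref_splicing(sets["Y"], catalogue, kinase)
        assert int(annotated["src_substrate"].sum()) == truth["n_src_sites"]
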