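import numpy as np
import pandas as pd
import pytest

from metatme.core import ValidationError, pos_col
from metatme.features import (
    assemble_features,
    compartment_proportions,
    count_ratios,
    feature_name,
    gcross_records,
    jsd_records,
    parse_feature_name,
    parse_phenotype_token,
    phenotype_token,
)


def _cells(panel, rows):
    """rows: list of (patient, compartment, cell_type, functional, metabolic)."""
    recs = []
    for i, (pat, comp, ct, fn, mb) in enumerate(rows):
        rec = {
            "core_id": pat, "patient_id": pat, "cell_id": i,
            "x_um": float(i), "y_um": 0.0, "cell_type": ct,
            "cn2_label": comp, "functional_states": fn, "metabolic_states": mb,
        }
        recs.append(rec)
    return pd.DataFrame(recs)


class TestProportions:
    def test_simple_fractions(self, panel):
        cells = _cells(panel, [
            ("p1", "tumor", "tumor", "", ""),
            ("p1", "tumor", "tumor", "", ""),
            ("p1", "tumor", "tumor", "", ""),
            ("p1", "tumor", "b_cell", "", ""),
        ])
        rec = compartment_proportions(cells, "cn2_label", "base", panel)
        vals = rec.set_index("feature")["value"]
        assert vals[feature_name("prop.cn2", "tumor", "tumor")] == 0.75
        assert vals[feature_name("prop.cn2", "tumor", "b_cell")] == 0.25

    def test_base_proportions_sum_to_one(self, panel, small_cohort):
        cells, _ = small_cohort
        cells = cells.copy()
        cells["cn2_label"] = np.where(cells["true_region"] == "nest", "tumor", "stroma")
        rec = compartment_proportions(cells, "cn2_label", "base", panel)
        rec["compartment"] = [parse_feature_name(f)[1] for f in rec["feature"]]
        sums = rec[rec["compartment"] == "tumor"].groupby("patient_id")["value"].sum()
        assert np.allclose(sums, 1.0)

    def test_absent_phenotype_zero_not_null(self, panel):
        cells = _cells(panel, [("p1", "tumor", "tumor", "", "")])
        rec = compartment_proportions(cells, "cn2_label", "base", panel)
        vals = rec.set_index("feature")["value"]
        assert vals[feature_name("prop.cn2", "tumor", "cd8_t")] == 0.0


class TestRatios:
    def test_count_ratio_and_reciprocal(self, panel):
        rows = [("p1", "tumor", "granulocyte", "", "")] * 4 + [
            ("p1", "tumor", "cd8_t", "", "")
        ] * 2
        rec = count_ratios(_cells(panel, rows), "cn2_label", panel=panel)
        vals = rec.set_index("feature")["value"]
        ab = vals[feature_name("ratio.cn2", "tumor", "granulocyte", "cd8_t")]
        ba = vals[feature_name("ratio.cn2", "tumor", "cd8_t", "granulocyte")]
        assert ab == 2.0
        assert ab * ba == pytest.approx(1.0)

    def test_zero_denominator_null(self, panel):
        rec = count_ratios(
            _cells(panel, [("p1", "tumor", "tumor", "", "")]),
            "cn2_label", panel=panel,
        )
        vals = rec.set_index("feature")["value"]
        assert np.isnan(vals[feature_name("ratio.cn2", "tumor", "tumor", "b_cell")])


class TestFeatureNames:
    @pytest.mark.parametrize("parts", [
        ("gcross.cn3", "interface", "macrophage+GranzymeB", "tumor"),
        ("prop.mbn", "low", "b_cell", ""),
        ("jsd.cn2", "stroma", "tumor+GLUT1.G6PD", "cd8_t+PD1"),
    ])
    def test_round_trip(self, parts):
        assert parse_feature_name(feature_name(*parts)) == parts

    def test_phenotype_token_round_trip(self):
        token = phenotype_token("macrophage", ("GranzymeB",))
        assert parse_phenotype_token(token) == ("macrophage", ("GranzymeB",))

    def test_separator_rejected_in_token(self):
        with pytest.raises(ValidationError):
            feature_name("prop|x", "a", "b")


class TestAssembly:
    def _records(self):
        rows = []
        for i, p in enumerate(f"p{j}" for j in range(30)):
            rows.append((p, "jsd.cn2|tumor|a|b", "jsd.cn2",
                         np.nan if i == 0 else 0.01 * i))
            rows.append((p, "gcross.cn2|tumor|a|b", "gcross.cn2",
                         np.nan if i == 1 else 0.02 * i))
            rows.append((p, "prop.cn2|tumor|a|", "prop.cn2", 0.5))  # constant
        return pd.DataFrame(
            rows, columns=["patient_id", "feature", "family", "value"]
        )

    def test_imputation_rules(self):
        fm = assemble_features(self._records(), [f"p{j}" for j in range(30)],
                               min_unique=5)
        assert fm.raw.loc["p0", "jsd.cn2|tumor|a|b"] == 1.0   # null JSD -> 1
        assert fm.raw.loc["p1", "gcross.cn2|tumor|a|b"] == 0.0  # other null -> 0

    def test_constant_feature_dropped(self):
        fm = assemble_features(self._records(), [f"p{j}" for j in range(30)],
                               min_unique=5)
        assert "prop.cn2|tumor|a|" in fm.dropped
        assert "prop.cn2|tumor|a|" not in fm.raw.columns

    def test_scaled_columns_standardized(self):
        fm = assemble_features(self._records(), [f"p{j}" for j in range(30)],
                               min_unique=5)
        assert np.allclose(fm.scaled.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(fm.scaled.std(axis=0, ddof=0), 1.0, atol=1e-9)

    def test_record_order_irrelevant(self):
        rec = self._records()
        fm1 = assemble_features(rec, [f"p{j}" for j in range(30)], min_unique=5)
        fm2 = assemble_features(rec.sample(frac=1.0, random_state=0),
                                [f"p{j}" for j in range(30)], min_unique=5)
        pd.testing.assert_frame_equal(fm1.scaled, fm2.scaled)

    def test_duplicate_record_rejected(self):
        rec = self._records()
        dup = pd.concat([rec, rec.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValidationError, match="duplicate"):
            assemble_features(dup, [f"p{j}" for j in range(30)], min_unique=5)

    def test_unique_value_filter_threshold(self):
        # 30 patients; a feature with only 10 distinct values is dropped at 25
        rows = [(f"p{j}", "prop.cn2|t|x|", "prop.cn2", j % 10) for j in range(30)]
        rows += [(f"p{j}", "prop.cn2|t|y|", "prop.cn2", float(j)) for j in range(30)]
        rec = pd.DataFrame(rows, columns=["patient_id", "feature", "family", "value"])
        fm = assemble_features(rec, [f"p{j}" for j in range(30)], min_unique=25)
        assert "prop.cn2|t|x|" in fm.dropped
        assert "prop.cn2|t|y|" in fm.features


def test_spatial_records_on_cohort(panel, small_cohort):
    cells, _ = small_cohort
    cells = cells.copy()
    cells["cn2_label"] = np.where(cells["true_region"] == "nest", "tumor", "stroma")
    g = gcross_records(cells, "cn2_label", panel, level="base")
    assert (g["value"].between(0, 1)).all()
    assert g["feature"].str.startswith("gcross.cn2|").all()
    j = jsd_records(cells.head(900), "cn2_label", panel, level="base", grid_size=32)
    assert (j["value"].between(0, 1)).all()


def test_feature_count_reproducible(panel, small_cohort):
    cells, clinical = small_cohort
    cells = cells.copy()
    cells["cn2_label"] = np.where(cells["true_region"] == "nest", "tumor", "stroma")
    rec1 = compartment_proportions(cells, "cn2_label", "base", panel)
    rec2 = compartment_proportions(cells, "cn2_label", "base", panel)
    fm1 = assemble_features(rec1, clinical.patient_id, min_unique=5)
    fm2 = assemble_features(rec2, clinical.patient_id, min_unique=5)
    assert fm1.features == fm2.features
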