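import numpy as np
import pandas as pd
import pytest

import hdabquant as hq
from hdabquant.batch import write_results_file
from hdabquant.detection import DetectionObject, LABEL_NEGATIVE, LABEL_NOCELL, LABEL_POSITIVE
from hdabquant.errors import DialectError, HdabQuantError, IntegrityError
from hdabquant.postprocess import (
    read_inventory,
    strip_vendor_suffix,
    write_positivity_table,
)


def _objs(n_pos, n_neg, n_no, region="tissue"):
    objs = []
    for i, (n, lab) in enumerate(
        [(n_pos, LABEL_POSITIVE), (n_neg, LABEL_NEGATIVE), (n_no, LABEL_NOCELL)]
    ):
        for j in range(n):
            o = DetectionObject(
                object_id=f"o{i}-{j}", centroid_um=(float(j), float(i)),
                nucleus_polygon=None, cell_polygon=None,
                label=lab, parent_region=region,
            )
            o.features = {f: 1.5 for f in hq.FEATURE_NAMES}
            objs.append(o)
    return objs


@pytest.fixture
def results_folder(tmp_path):
    write_results_file(_objs(10, 30, 5), {"image": "A"}, tmp_path / "A.mrxs.txt")
    write_results_file(_objs(4, 4, 0), {"image": "B"}, tmp_path / "B.ndpi.txt")
    return tmp_path


@pytest.mark.parametrize(
    "name, expected",
    [("A.mrxs", "A"), ("B.ndpi", "B"), ("C.czi", "C"), ("D.bif", "D"), ("E", "E"),
     ("sample.v2", "sample.v2")],
)
def test_vendor_suffix_stripping(name, expected):
    assert strip_vendor_suffix(name) == expected


def test_parse_results_ids_and_counts(results_folder):
    det = hq.parse_results(results_folder)
    assert set(det["ID_Slidescanning"]) == {"A", "B"}
    assert len(det) == 45 + 8
    counts = det["Classification"].value_counts()
    assert counts[LABEL_POSITIVE] == 14 and counts[LABEL_NEGATIVE] == 34


def test_parse_skips_malformed_rows(results_folder):
    with open(results_folder / "A.mrxs.txt", "a", encoding="utf-8") as fh:
        fh.write("garbage\tthat\tis\tnot\ta\trow\n")
    det = hq.parse_results(results_folder)
    assert det.attrs["n_skipped"] == 1
    assert len(det) == 45 + 8


def test_parse_rejects_unknown_header(tmp_path):
    (tmp_path / "X.txt").write_text("Image\tBogus Column\nA\t1\n")
    with pytest.raises(DialectError):
        hq.parse_results(tmp_path)


def test_parse_empty_folder_errors(tmp_path):
    with pytest.raises(HdabQuantError):
        hq.parse_results(tmp_path)


def test_write_parse_round_trip_conserves_class_counts(tmp_path):
    objs = _objs(17, 23, 9)
    write_results_file(objs, {"image": "S"}, tmp_path / "S.txt")
    det = hq.parse_results(tmp_path)
    counts = det["Classification"].value_counts()
    assert counts[LABEL_POSITIVE] == 17
    assert counts[LABEL_NEGATIVE] == 23
    assert counts[LABEL_NOCELL] == 9
    assert len(det) == len(objs)


def _inventory(ids, antibody="COL2"):
    return pd.DataFrame(
        {
            "ID_Slidescanning": ids,
            "sample_id": [f"s{i}" for i in range(len(ids))],
            "antibody": antibody,
        }
    )


def test_merge_conserves_rows_and_warns_on_unmatched(results_folder, caplog):
    det = hq.parse_results(results_folder)
    inv = _inventory(["A"])  # B missing
    with caplog.at_level("WARNING"):
        merged = hq.merge_inventory(det, inv)
    assert len(merged) == len(det)
    assert merged.attrs["unmatched"] == ["B"]
    assert merged.loc[merged["ID_Slidescanning"] == "B", "sample_id"].isna().all()


def test_merge_rejects_duplicate_keys(results_folder):
    det = hq.parse_results(results_folder)
    with pytest.raises(IntegrityError):
        hq.merge_inventory(det, _inventory(["A", "A"]))


def test_positivity_table_rates_and_conservation(results_folder):
    det = hq.parse_results(results_folder)
    merged = hq.merge_inventory(det, _inventory(["A", "B"]))
    table = hq.positivity_table(merged)
    a = table[table["ID_Slidescanning"] == "A"].iloc[0]
    assert a["positivity_rate"] == pytest.approx(25.0)
    assert a["n_nocell"] == 5
    total = (table["n_positive"] + table["n_negative"] + table["n_nocell"]).sum()
    assert total == len(det)


def test_positivity_table_flags_all_nocell_group(tmp_path):
    write_results_file(_objs(0, 0, 7), {"image": "Z"}, tmp_path / "Z.txt")
    det = hq.parse_results(tmp_path)
    table = hq.positivity_table(hq.merge_inventory(det, _inventory(["Z"])))
    assert bool(table["undefined"].iloc[0])
    assert np.isnan(table["positivity_rate"].iloc[0])


def test_write_positivity_table_csv_and_xlsx(tmp_path, results_folder):
    det = hq.parse_results(results_folder)
    table = hq.positivity_table(hq.merge_inventory(det, _inventory(["A", "B"])))
    csv = write_positivity_table(table, tmp_path / "p.csv")
    xlsx = write_positivity_table(table, tmp_path / "p.xlsx")
    assert pd.read_csv(csv).shape[0] == table.shape[0]
    assert pd.read_excel(xlsx).shape[0] == table.shape[0]


@pytest.fixture
def markers():
    rng = np.random.default_rng(12)
    a = rng.uniform(0, 100, 20)
    return pd.DataFrame(
        {"A": a, "B": 2 * a % 100, "C": rng.uniform(0, 100, 20)},
        index=[f"s{i}" for i in range(20)],
    )


def test_correlation_perfect_linear_and_monotone():
    a = np.linspace(1, 50, 10)
    m = pd.DataFrame({"A": a, "B": 2 * a, "C": np.exp(a / 20)})
    corr_p, _ = hq.correlation_matrix(m, "pearson")
    assert corr_p.loc["A", "B"] == pytest.approx(1.0)
    corr_s, _ = hq.correlation_matrix(m, "spearman")
    assert corr_s.loc["A", "C"] == pytest.approx(1.0)


def test_correlation_matches_direct_formula_oracle(markers):
    corr, n = hq.correlation_matrix(markers, "pearson")
    for a in markers.columns:
        for b in markers.columns:
            x, y = markers[a].to_numpy(), markers[b].to_numpy()
            expect = (
                ((x - x.mean()) * (y - y.mean())).sum()
                / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
            )
            if a == b:
                expect = 1.0
            assert corr.loc[a, b] == pytest.approx(expect, abs=1e-12)
            assert corr.loc[a, b] == corr.loc[b, a]
            assert abs(corr.loc[a, b]) <= 1.0
            assert n.loc[a, b] == 20


def test_correlation_pairwise_n_and_min_pairs():
    m = pd.DataFrame({"A": [1, 2, 3, 4, 5], "B": [2, 4, 6, 8, 10], "C": [1, 2, np.nan, np.nan, np.nan]})
    corr, n = hq.correlation_matrix(m)
    assert n.loc["A", "C"] == 2
    assert np.isnan(corr.loc["A", "C"])  # fewer than 3 complete pairs
    assert corr.loc["A", "B"] == pytest.approx(1.0)


def test_correlation_constant_column_warns():
    m = pd.DataFrame({"A": [1.0, 2, 3, 4], "B": [5.0, 5, 5, 5], "C": [2.0, 1, 4, 3]})
    with pytest.warns(UserWarning, match="constant"):
        corr, _ = hq.correlation_matrix(m)
    assert np.isnan(corr.loc["A", "B"])
    assert corr.loc["B", "B"] == 1.0


def test_correlation_requires_two_markers(markers):
    with pytest.raises(HdabQuantError):
        hq.correlation_matrix(markers[["A"]])


def test_render_outputs_file_sets(tmp_path, markers):
    corr, _ = hq.correlation_matrix(markers)
    files = hq.render_outputs(markers, corr, tmp_path / "plots")
    names = sorted(f.name for f in files)
    assert "correlation_heatmap.png" in names
    assert len([n for n in names if "_vs_" in n]) == 3  # 3 choose 2
    again = hq.render_outputs(markers, corr, tmp_path / "plots")
    assert sorted(f.name for f in again) == names


def test_render_single_marker_heatmap_only(tmp_path, markers):
    m = markers[["A"]]
    corr = pd.DataFrame([[1.0]], index=["A"], columns=["A"])
    files = hq.render_outputs(m, corr, tmp_path / "one")
    assert [f.name for f in files] == ["correlation_heatmap.png"]


def test_inventory_reader_requires_key(tmp_path):
    p = tmp_path / "inv.csv"
    pd.DataFrame({"sample_id": ["a"]}).to_csv(p, index=False)
    with pytest.raises(DialectError):
        read_inventory(p)
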