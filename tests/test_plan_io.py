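"""Plan-bundle dialect round-trips, validation errors, POI query grammar,
and the spreadsheet-style report."""

import numpy as np
import pytest

from dvhkit.errors import (
    BundleMalformedError,
    DanglingStructureError,
    GridInconsistentError,
    PoiParseError,
)
from dvhkit.grid import DoseGrid, StructureContours
from dvhkit.phantom import PhantomSpec, make_phantom_plan
from dvhkit.plan_io import (
    PlanBundle,
    PlanRecord,
    PlanReport,
    TargetRow,
    parse_poi_token,
    read_plan_bundle,
    read_poi_config,
    write_plan_bundle,
    write_report,
)
from dvhkit.report import build_report


@pytest.fixture()
def small_bundle():
    rng = np.random.default_rng(0)
    grid1 = DoseGrid(origin=np.zeros(3), spacing=np.array([2.0, 2.0, 3.0]),
                     dose=rng.uniform(0, 4000, size=(4, 5, 6)))
    grid2 = DoseGrid(origin=np.zeros(3), spacing=np.array([2.0, 2.0, 3.0]),
                     dose=rng.uniform(0, 1500, size=(4, 5, 6)))
    ring = np.array([[1.0, 1.0], [9.0, 1.0], [9.0, 7.0], [1.0, 7.0]])
    s = StructureContours("PTV", [(0.0, [ring]), (3.0, [ring])], role="target")
    plans = [PlanRecord("PTV1", 3900.0), PlanRecord("PTV2", 1500.0),
             PlanRecord("COMP", 5400.0, components=("PTV1", "PTV2"))]
    grids = {"PTV1": grid1, "PTV2": grid2,
             "COMP": DoseGrid(origin=np.zeros(3), spacing=np.array([2.0, 2.0, 3.0]),
                              dose=grid1.dose + grid2.dose)}
    return PlanBundle(plans=plans, structures=[s], grids=grids)


class TestBundleRoundTrip:
    def test_write_then_read_is_identity(self, small_bundle, tmp_path):
        write_plan_bundle(small_bundle, tmp_path / "b")
        assert read_plan_bundle(tmp_path / "b") == small_bundle

    def test_composite_prescription_is_component_sum(self, small_bundle, tmp_path):
        write_plan_bundle(small_bundle, tmp_path / "b")
        back = read_plan_bundle(tmp_path / "b")
        assert back.plan("COMP").prescription_dose == pytest.approx(3900.0 + 1500.0)

    def test_phantom_bundle_contract(self, tmp_path):
        """The default sphere phantom (seed 42) round-trips with one plan
        and two structures."""
        write_plan_bundle(make_phantom_plan(PhantomSpec(seed=42)), tmp_path / "p")
        bundle = read_plan_bundle(tmp_path / "p")
        assert len(bundle.plans) == 1
        assert sorted(s.name for s in bundle.structures) == ["OAR", "PTV"]


class TestBundleErrors:
    def test_missing_header(self, tmp_path):
        with pytest.raises(BundleMalformedError, match="bundle malformed"):
            read_plan_bundle(tmp_path)

    def test_missing_dose_file(self, small_bundle, tmp_path):
        write_plan_bundle(small_bundle, tmp_path / "b")
        (tmp_path / "b" / "dose_PTV1.txt").unlink()
        with pytest.raises(GridInconsistentError, match="grid inconsistent"):
            read_plan_bundle(tmp_path / "b")

    def test_dose_size_mismatch(self, small_bundle, tmp_path):
        write_plan_bundle(small_bundle, tmp_path / "b")
        p = tmp_path / "b" / "dose_PTV1.txt"
        lines = p.read_text().splitlines()
        p.write_text("\n".join(lines[:-2]) + "\n")
        with pytest.raises(GridInconsistentError, match="grid inconsistent"):
            read_plan_bundle(tmp_path / "b")

    def test_missing_contour_file(self, small_bundle, tmp_path):
        write_plan_bundle(small_bundle, tmp_path / "b")
        (tmp_path / "b" / "roi_PTV.txt").unlink()
        with pytest.raises(DanglingStructureError, match="dangling structure"):
            read_plan_bundle(tmp_path / "b")


class TestPoiGrammar:
    def test_vx_queries(self, tmp_path):
        p = tmp_path / "poi.txt"
        p.write_text("V40,V50,V65,V75\n")
        queries = read_poi_config(p)
        assert [q.kind for q in queries] == ["volume_at_dose"] * 4
        assert [q.dose_cgy for q in queries] == [4000.0, 5000.0, 6500.0, 7500.0]

    def test_pd_relative_resolution(self, tmp_path):
        p = tmp_path / "poi.txt"
        p.write_text(">0.25PD\n")
        (q,) = read_poi_config(p, pd=3900.0)
        assert q.dose_cgy == pytest.approx(975.0)

    def test_dx_and_stats(self):
        assert parse_poi_token("D95").volume_pct == 95.0
        assert parse_poi_token("median").stat == "median"

    def test_empty_file(self, tmp_path):
        p = tmp_path / "poi.txt"
        p.write_text("# nothing here\n\n")
        assert read_poi_config(p) == []

    def test_malformed_token_named_in_error(self):
        with pytest.raises(PoiParseError, match="Q17"):
            parse_poi_token("Q17")


class TestReport:
    def _rows(self):
        # absolute covered volumes chosen to exercise integer-percent rounding
        return PlanReport(targets=[
            TargetRow("ABC", "PTV1", 3900.0, 131.6, 4352.1, 4072.6, 1391.5,
                      {">1.05PD": 652.7, "<0.93PD": 28.1}),
            TargetRow("ABC", "PTV2", 1500.0, 95.4, 1650.5, 1559.4, 624.4,
                      {">1.05PD": 241.0}),
            TargetRow("ABC", "PTV3", 1950.0, 216.3, 2145.5, 2027.2, 308.6,
                      {">1.05PD": 124.7}),
        ], organs=[], stats=[])

    def test_normalized_cells_round_half_up(self, tmp_path):
        write_report(self._rows(), tmp_path)
        text = (tmp_path / "report_targets.csv").read_text()
        lines = [l for l in text.splitlines() if l.startswith("ABC,PTV")]
        # last six cells of the normalized block
        norm = lines[6:9]
        assert norm[0].split(",")[4] == "47%"
        assert norm[1].split(",")[4] == "39%"
        assert norm[2].split(",")[4] == "40%"

    def test_rerun_byte_identical(self, tmp_path, uniform_bundle):
        rep = build_report(uniform_bundle, patient="CASE")
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        write_report(rep, d1)
        write_report(rep, d2)
        for f in d1.iterdir():
            assert f.read_bytes() == (d2 / f.name).read_bytes()

    def test_uniform_phantom_target_row_equals_pd(self, tmp_path, uniform_bundle):
        rep = build_report(uniform_bundle, patient="CASE")
        row = rep.targets[0]
        assert row.min_dose == row.max_dose == row.mean_dose == 3900.0

    def test_empty_report_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_report(PlanReport(targets=[], organs=[], stats=[]), tmp_path)
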