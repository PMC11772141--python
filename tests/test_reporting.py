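import numpy as np
import pytest
import tifffile

from myofiber_morph import (BatchConfig, ChannelMap, DatasetError,
                            PixelScale, SizeLimits, run_batch)
from myofiber_morph.morphometry import FiberRecord
from myofiber_morph.reporting import (render_final_overlay,
                                      write_fiber_outputs)


def _config(folder, with_intensity=True, **kw):
    return BatchConfig(
        main_folder=folder,
        channels=ChannelMap("Laminin", "DAPI",
                            "RFP" if with_intensity else None),
        scale=PixelScale(1.0),
        limits=SizeLimits(200, 4800),
        **kw)


class TestOverlay:
    def _fibers(self):
        lm = np.zeros((64, 64), dtype=int)
        lm[4:20, 4:20] = 1
        lm[4:20, 30:46] = 2
        lm[30:46, 4:20] = 3
        fibers = [FiberRecord(number=k, label=k, csa_um2=256.0, area_px=256,
                              centroid=(12.0, [12, 38, 12][k - 1])
                              if k < 3 else (38.0, 12.0))
                  for k in (1, 2, 3)]
        return lm, fibers

    def test_zero_fibers_backdrop_only(self, tmp_path):
        img = np.full((32, 32), 80, dtype=np.uint8)
        path = render_final_overlay(img, np.zeros((32, 32), int), [],
                                    tmp_path / "final.tif")
        out = tifffile.imread(path)
        assert out.shape == (32, 32, 3)
        # pure grayscale backdrop: all three planes equal
        assert (out[..., 0] == out[..., 1]).all()

    def test_numbers_drawn_at_centroids(self, tmp_path):
        lm, fibers = self._fibers()
        backdrop = np.zeros((64, 64), dtype=np.uint8)
        out = tifffile.imread(render_final_overlay(
            backdrop, lm, fibers, tmp_path / "final.tif"))
        for f in fibers:
            r, c = int(f.centroid[0]), int(f.centroid[1])
            patch = out[r - 6:r + 6, c - 6:c + 6]
            assert (patch == [255, 255, 0]).all(axis=-1).any()

    def test_rerun_byte_identical(self, tmp_path):
        lm, fibers = self._fibers()
        backdrop = (lm * 60).astype(np.uint8)
        a = render_final_overlay(backdrop, lm, fibers, tmp_path / "a.tif")
        b = render_final_overlay(backdrop, lm, fibers, tmp_path / "b.tif")
        assert a.read_bytes() == b.read_bytes()


class DummyJob:
    def __init__(self, folder):
        self.folder = folder
        self.name = folder.name


class TestFiberOutputs:
    def test_csv_contract_without_mfi(self, tmp_path):
        job_dir = tmp_path / "Sample"
        job_dir.mkdir()
        fibers = [FiberRecord(1, 1, 350.0, 350, (0, 0), cnf=True),
                  FiberRecord(2, 2, 1200.0, 1200, (0, 0), cnf=False)]
        bundle = write_fiber_outputs(DummyJob(job_dir), fibers,
                                     tmp_path / "Results")
        assert bundle.csa_csv_path.read_text() == "350.0,1200.0\n"
        assert bundle.mfi_csv_path is None
        rows = bundle.fiber_table_path.read_text().splitlines()
        assert rows[0] == "fiber\tcsa_um2\tcnf"
        assert rows[1] == "1\t350.0\tTRUE"
        assert rows[2] == "2\t1200.0\tFALSE"

    def test_mfi_adds_file_and_column(self, tmp_path):
        job_dir = tmp_path / "Sample"
        job_dir.mkdir()
        fibers = [FiberRecord(1, 1, 350.0, 350, (0, 0), cnf=False, mfi=55.5)]
        bundle = write_fiber_outputs(DummyJob(job_dir), fibers,
                                     tmp_path / "Results")
        assert bundle.mfi_csv_path.read_text() == "55.5\n"
        rows = bundle.fiber_table_path.read_text().splitlines()
        assert rows[0].endswith("\tmfi_au")
        assert rows[1].split("\t") == ["1", "350.0", "FALSE", "55.5"]

    def test_zero_fibers_header_only(self, tmp_path):
        job_dir = tmp_path / "Empty"
        job_dir.mkdir()
        bundle = write_fiber_outputs(DummyJob(job_dir), [],
                                     tmp_path / "Results")
        assert bundle.csa_csv_path.read_text().strip() == ""
        assert bundle.fiber_table_path.read_text().splitlines() == [
            "fiber\tcsa_um2\tcnf"]


class TestRunBatch:
    def test_two_jobs_full_contract(self, fixture_batch):
        summary = run_batch(_config(fixture_batch))
        assert len(summary.results) == 2
        results_dir = fixture_batch / "Results"
        for r in summary.results:
            name = r.job.name
            assert (r.job.folder / "final.tif").exists()
            csa = (results_dir / f"{name}_CSA.csv").read_text().strip()
            mfi = (results_dir / f"{name}_MFI.csv").read_text().strip()
            table = (results_dir / f"{name}_fibers.txt").read_text()
            n = len(r.fibers)
            assert len(csa.split(",")) == n
            assert len(mfi.split(",")) == n
            assert len(table.splitlines()) == n + 1
            # summary stats exist and are in range
            assert r.mean_csa > 0 and 0 <= r.pct_cnf <= 100

    def test_partial_batch_survives_bad_folder(self, fixture_batch):
        # a folder missing the boundary channel is reported, not fatal
        bad = fixture_batch / "scene_000_bad"
        bad.mkdir()
        (bad / "DAPI.tif").write_bytes(
            (fixture_batch / "scene_001" / "DAPI.tif").read_bytes())
        summary = run_batch(_config(fixture_batch))
        assert len(summary.results) == 2
        assert any(name == "scene_000_bad" for name, _ in summary.errors)

    def test_empty_main_folder_fatal_no_results_dir(self, tmp_path):
        main = tmp_path / "main"
        main.mkdir()
        with pytest.raises(DatasetError):
            run_batch(_config(main))
        assert not (main / "Results").exists()

    def test_reruns_byte_identical_outputs(self, fixture_batch):
        run_batch(_config(fixture_batch))
        results_dir = fixture_batch / "Results"
        first = {p.name: p.read_bytes() for p in results_dir.iterdir()}
        overlay1 = (fixture_batch / "scene_001" / "final.tif").read_bytes()
        run_batch(_config(fixture_batch))
        second = {p.name: p.read_bytes() for p in results_dir.iterdir()}
        assert first == second
        assert overlay1 == (fixture_batch / "scene_001" /
                            "final.tif").read_bytes()
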