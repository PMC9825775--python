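"""Job execution and pipeline scheduling: lifecycle, policies, arithmetic."""

import os

import pytest

from percell import (
    ConfigurationError,
    EventLog,
    JobSpec,
    RunConfig,
    execute_job,
    run_pipeline,
)

from conftest import scbam_records


def make_scbam(tmp_path, name="cell.bam"):
    """A minimal stand-in scBAM file; jobs only need it to exist."""
    import pysam

    path = str(tmp_path / name)
    header = {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": "1", "LN": 100}]}
    with pysam.AlignmentFile(path, "wb", header=header):
        pass
    return path


class TestExecuteJob:
    def test_success_deletes_scbam(self, tmp_path):
        path = make_scbam(tmp_path)
        result = execute_job(JobSpec("b1", path, "exit 0"))
        assert result.exit_code == 0 and result.ok
        assert not os.path.exists(path)

    def test_nonzero_exit_recorded_not_raised(self, tmp_path):
        path = make_scbam(tmp_path)
        result = execute_job(JobSpec("b1", path, "exit 3"))
        assert result.exit_code == 3 and not result.ok

    def test_keep_scbam_survives(self, tmp_path):
        path = make_scbam(tmp_path)
        execute_job(JobSpec("b1", path, "true", keep_scbam=True))
        assert os.path.exists(path)

    def test_index_first_builds_bai_then_cleans_both(self, tmp_path):
        path = make_scbam(tmp_path)
        probe = tmp_path / "probe"
        execute_job(
            JobSpec(
                "b1",
                path,
                f"test -e {path}.bai && touch {probe}",
                index_first=True,
            )
        )
        assert probe.exists()  # index existed while the command ran
        assert not os.path.exists(path) and not os.path.exists(path + ".bai")

    def test_pipes_and_redirection_work_in_workdir(self, tmp_path):
        path = make_scbam(tmp_path)
        workdir = str(tmp_path / "work")
        result = execute_job(
            JobSpec("ACGT", path, f"cat {path} | wc -c > ACGT.size", workdir=workdir)
        )
        assert result.ok
        size = int((tmp_path / "work" / "ACGT.size").read_text())
        assert size > 0

    def test_stdout_stderr_paths(self, tmp_path):
        path = make_scbam(tmp_path)
        out, err = str(tmp_path / "o.txt"), str(tmp_path / "e.txt")
        result = execute_job(
            JobSpec("b1", path, "echo OUT; echo ERR 1>&2", stdout_path=out, stderr_path=err)
        )
        assert result.ok
        assert open(out).read() == "OUT\n"
        assert open(err).read() == "ERR\n"

    def test_unwritable_stdout_marks_job_failed_with_reason(self, tmp_path):
        path = make_scbam(tmp_path)
        result = execute_job(
            JobSpec("b1", path, "true", stdout_path="/proc/definitely/not/writable")
        )
        assert not result.ok
        assert result.failure_reason is not None


class TestPipeline:
    def run(self, bam, tmp_path, **kwargs):
        defaults = dict(
            input_bam=bam,
            command_template="true",
            batch_size=2,
            jobs=2,
            scratch_dir=str(tmp_path / "scratch"),
        )
        defaults.update(kwargs)
        ev = EventLog()
        summary = run_pipeline(RunConfig(**defaults), event_log=ev)
        return summary, ev

    def test_job_and_scan_arithmetic(self, make_fixture, tmp_path):
        bam, truth = make_fixture(n_barcodes=5, reads_per_barcode=4)
        summary, ev = self.run(bam, tmp_path)
        assert summary.jobs_launched == 5
        assert summary.jobs_succeeded == 5
        assert summary.scans == 3 == ev.count("scan_start")
        assert summary.barcodes == truth.order
        assert summary.stats.consistent
        assert summary.fatal_error is None

    def test_limit_caps_jobs(self, make_fixture, tmp_path):
        bam, _ = make_fixture(n_barcodes=5, reads_per_barcode=4)
        summary, _ = self.run(bam, tmp_path, limit=3)
        assert summary.jobs_launched == 3

    def test_failures_recorded_run_continues_by_default(self, make_fixture, tmp_path):
        bam, _ = make_fixture(n_barcodes=4, reads_per_barcode=3)
        summary, _ = self.run(bam, tmp_path, command_template="exit 3")
        assert summary.jobs_launched == 4
        assert summary.jobs_failed == 4
        assert {r.exit_code for r in summary.results} == {3}
        assert summary.fatal_error is None

    def test_fail_fast_stops_launching(self, make_fixture, tmp_path):
        bam, _ = make_fixture(n_barcodes=6, reads_per_barcode=3)
        summary, ev = self.run(
            bam, tmp_path, command_template="exit 1", fail_fast=True, jobs=1,
            batch_size=1,
        )
        assert summary.jobs_failed >= 1
        assert summary.jobs_launched < 6

    def test_acceptlist_restricts_and_absent_barcode_skipped(
        self, make_fixture, tmp_path
    ):
        bam, truth = make_fixture(n_barcodes=4, reads_per_barcode=3)
        acceptlist = tmp_path / "accept.tsv"
        listed = [truth.order[0], "NOTINBAM", truth.order[2]]
        acceptlist.write_text("".join(b + "\n" for b in listed))
        keep_dir = tmp_path / "kept"
        keep_dir.mkdir()
        summary, _ = self.run(
            bam,
            tmp_path,
            acceptlist_path=str(acceptlist),
            file_template=str(keep_dir / "{BARCODE}.bam"),
        )
        assert summary.barcodes == listed
        assert summary.jobs_launched == 2
        assert summary.barcodes_skipped_empty == 1
        emitted = sorted(p.name for p in keep_dir.iterdir())
        assert emitted == sorted(f"{b}.bam" for b in (listed[0], listed[2]))

    def test_emit_empty_schedules_header_only_jobs(self, make_fixture, tmp_path):
        bam, truth = make_fixture(n_barcodes=2, reads_per_barcode=3)
        acceptlist = tmp_path / "accept.tsv"
        acceptlist.write_text(f"{truth.order[0]}\nGHOSTBARCODE\n")
        keep_dir = tmp_path / "kept"
        keep_dir.mkdir()
        summary, _ = self.run(
            bam,
            tmp_path,
            acceptlist_path=str(acceptlist),
            emit_empty=True,
            file_template=str(keep_dir / "{BARCODE}.bam"),
        )
        assert summary.jobs_launched == 2
        assert summary.barcodes_skipped_empty == 0
        assert scbam_records(str(keep_dir / "GHOSTBARCODE.bam")) == []

    def test_scratch_dir_left_empty_without_file_template(self, make_fixture, tmp_path):
        bam, _ = make_fixture(n_barcodes=3, reads_per_barcode=3)
        summary, _ = self.run(bam, tmp_path, index=True)
        assert summary.jobs_succeeded == 3
        assert os.listdir(tmp_path / "scratch") == []

    def test_per_job_stdout_template(self, make_fixture, tmp_path):
        bam, truth = make_fixture(n_barcodes=3, reads_per_barcode=3)
        outdir = tmp_path / "logs"
        summary, _ = self.run(
            bam,
            tmp_path,
            command_template="echo {BARCODE}",
            stdout_template=str(outdir / "{BARCODE}.out"),
        )
        for barcode in truth.order:
            assert (outdir / f"{barcode}.out").read_text() == barcode + "\n"

    def test_restart_determinism_across_p_and_b(self, make_fixture, tmp_path):
        """(barcode, exit code) pairs do not depend on parallelism or batching."""
        bam, _ = make_fixture(n_barcodes=5, reads_per_barcode=4)
        command = 'test $(samtools view -c {}) -eq 4'
        outcomes = []
        for jobs, batch in [(1, 1), (3, 2), (2, 100)]:
            summary, _ = self.run(
                bam, tmp_path, command_template=command, jobs=jobs, batch_size=batch
            )
            outcomes.append({(r.barcode, r.exit_code) for r in summary.results})
        assert outcomes[0] == outcomes[1] == outcomes[2]
        assert all(code == 0 for _, code in outcomes[0])

    def test_index_flag_requires_coordinate_sorted_input(self, tmp_path):
        import pysam

        path = str(tmp_path / "unsorted.bam")
        header = {"HD": {"VN": "1.6", "SO": "queryname"}, "SQ": [{"SN": "1", "LN": 100}]}
        with pysam.AlignmentFile(path, "wb", header=header):
            pass
        with pytest.raises(ConfigurationError, match="coordinate"):
            run_pipeline(
                RunConfig(input_bam=path, command_template="true", index=True)
            )

    def test_extraction_error_reports_partial_summary(self, make_fixture, tmp_path):
        bam, truth = make_fixture(n_barcodes=4, reads_per_barcode=3)
        acceptlist = tmp_path / "accept.tsv"
        acceptlist.write_text("".join(b + "\n" for b in truth.order))
        # two barcodes sanitize to the same filename -> fatal during planning,
        # after validation but before any job
        acceptlist.write_text("A/B\nA:B\n")
        summary, _ = self.run(bam, tmp_path, acceptlist_path=str(acceptlist))
        assert summary.fatal_error is not None
        assert "collision" in summary.fatal_error
        assert summary.jobs_launched == 0
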