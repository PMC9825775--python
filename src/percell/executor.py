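"""Interleaved extraction and per-cell command execution.

The main thread is the producer: it scans the pooled BAM once per batch of
barcodes, writing the batch's scBAMs.  A worker pool of at most P threads is
the consumer: each worker launches one rendered command in a shell, waits for
it, and tears the scBAM down (index -> run -> delete unless kept).  Because
the producer submits a batch's jobs and immediately starts the next scan,
extraction of batch i+1 overlaps execution of batch i — there is at most one
active scan, and scans never wait for job completion.

With no acceptance list, barcode discovery is folded into the first scan:
pass 1 assigns first-seen indices, writes scBAMs for the first batch-size
barcodes, and memorizes the rest, so a run with n accepted barcodes and
batch size B costs exactly ceil(n/B) scans.

Job failures are recorded and the run continues by default — per-cell
analyses routinely fail for sparse cells, and one bad cell must not kill
thousands of jobs; ``fail_fast`` opts into stopping new launches after the
first nonzero exit.
"""

from __future__ import annotations

import os
import shutil
import subprocess
import tempfile
import threading
import time
from concurrent.futures import Future, ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import pysam

from .barcodes import extract_barcode
from .config import RunConfig
from .demux import (
    DEFAULT_SCBAM_TEMPLATE,
    DemuxStats,
    ScbamWriterSet,
    index_scbam,
    plan_batches,
    read_barcode_list,
    sanitize_barcode,
    scan_records,
)
from .errors import ConfigurationError, PercellError
from .events import EventLog
from .regions import Region, parse_regions
from .templating import TemplateContext, bambase_of, render, render_command


@dataclass(frozen=True)
class JobSpec:
    """One rendered command bound to one scBAM."""

    barcode: str
    scbam_path: str
    command: str
    workdir: Optional[str] = None  # None: inherit the current directory
    stdout_path: Optional[str] = None
    stderr_path: Optional[str] = None
    keep_scbam: bool = False
    index_first: bool = False


@dataclass(frozen=True)
class JobResult:
    barcode: str
    exit_code: int
    wall_seconds: float
    failure_reason: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.exit_code == 0 and self.failure_reason is None


@dataclass
class RunSummary:
    jobs_launched: int = 0
    jobs_succeeded: int = 0
    jobs_failed: int = 0
    barcodes_skipped_empty: int = 0
    stats: DemuxStats = field(default_factory=DemuxStats)
    barcodes: List[str] = field(default_factory=list)
    scans: int = 0
    results: List[JobResult] = field(default_factory=list)
    scbam_dir: Optional[str] = None
    fatal_error: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.fatal_error is None


def _open_sink(path: Optional[str]):
    if path is None:
        return None
    parent = os.path.dirname(path)
    if parent:
        os.makedirs(parent, exist_ok=True)
    return open(path, "wb")


def _remove_quiet(path: str) -> None:
    try:
        os.remove(path)
    except FileNotFoundError:
        pass


def execute_job(job: JobSpec) -> JobResult:
    """Run one job: optionally index, launch in a shell, wait, clean up.

    The command runs via the shell so pipes, list operators and redirection
    behave as in an interactive session.  The scBAM (and its index) is
    deleted after the process has exited unless ``keep_scbam``.  A nonzero
    exit code is recorded, never raised; only an unlaunchable shell is fatal.
    """
    t0 = time.monotonic()
    out = err = None
    try:
        try:
            if job.index_first:
                index_scbam(job.scbam_path)
            if job.workdir:
                os.makedirs(job.workdir, exist_ok=True)
            out = _open_sink(job.stdout_path)
            err = _open_sink(job.stderr_path)
        except OSError as exc:
            return JobResult(
                job.barcode,
                exit_code=-1,
                wall_seconds=time.monotonic() - t0,
                failure_reason=f"could not prepare job outputs: {exc}",
            )
        try:
            proc = subprocess.Popen(
                job.command,
                shell=True,
                cwd=job.workdir or None,
                stdout=out,
                stderr=err,
            )
        except OSError as exc:
            raise ConfigurationError(f"cannot start a shell: {exc}") from exc
        exit_code = proc.wait()
        return JobResult(job.barcode, exit_code, time.monotonic() - t0)
    finally:
        for sink in (out, err):
            if sink is not None:
                sink.close()
        if not job.keep_scbam:
            _remove_quiet(job.scbam_path)
            _remove_quiet(job.scbam_path + ".bai")


class _PathPlanner:
    """Lazy scBAM path planning with collision detection across the run."""

    def __init__(self, bambase: str, template: str, base_dir: Optional[str]):
        self._bambase = bambase
        self._template = template
        self._base_dir = base_dir
        self._paths: Dict[str, str] = {}
        self._reverse: Dict[str, str] = {}

    def path_for(self, barcode: str) -> str:
        path = self._paths.get(barcode)
        if path is not None:
            return path
        ctx = TemplateContext(
            scbam_path="", barcode=sanitize_barcode(barcode), bambase=self._bambase
        )
        path = render(self._template, ctx)
        if self._base_dir is not None and not os.path.isabs(path):
            path = os.path.join(self._base_dir, path)
        if path in self._reverse:
            raise ConfigurationError(
                f"scBAM filename collision after sanitization: barcodes "
                f"{self._reverse[path]!r} and {barcode!r} both map to {path}"
            )
        self._reverse[path] = barcode
        self._paths[barcode] = path
        return path


def _build_job(config: RunConfig, barcode: str, scbam_path: str, bambase: str) -> JobSpec:
    ctx = TemplateContext(
        scbam_path=os.path.abspath(scbam_path), barcode=barcode, bambase=bambase
    )
    return JobSpec(
        barcode=barcode,
        scbam_path=os.path.abspath(scbam_path),
        command=render_command(config.command_template, ctx),
        workdir=render(config.workdir_template, ctx) if config.workdir_template else None,
        stdout_path=render(config.stdout_template, ctx) if config.stdout_template else None,
        stderr_path=render(config.stderr_template, ctx) if config.stderr_template else None,
        keep_scbam=config.keep_scbams,
        index_first=config.index,
    )


def _job_worker(
    job: JobSpec, ev: EventLog, abort: threading.Event, fail_fast: bool
) -> Optional[JobResult]:
    if fail_fast and abort.is_set():
        ev.emit("job_skipped", barcode=job.barcode)
        if not job.keep_scbam:
            _remove_quiet(job.scbam_path)
            _remove_quiet(job.scbam_path + ".bai")
        return None
    ev.emit("job_start", barcode=job.barcode, command=job.command)
    result = execute_job(job)
    ev.emit(
        "job_end",
        barcode=job.barcode,
        exit_code=result.exit_code,
        wall_seconds=result.wall_seconds,
    )
    if not result.ok and fail_fast:
        abort.set()
    return result


def run_pipeline(config: RunConfig, event_log: Optional[EventLog] = None) -> RunSummary:
    """Run the whole engine: plan, scan per batch, execute one job per scBAM.

    Scheduling contract: at most ``config.jobs`` commands run concurrently;
    at most one extraction scan is active at a time; extraction of batch i+1
    may proceed while batch i's jobs run; all jobs have completed when the
    summary is returned.  An extraction error aborts subsequent batches,
    waits for in-flight jobs, and is reported in ``fatal_error``.
    """
    ev = event_log if event_log is not None else EventLog(config.event_log_path)
    own_log = event_log is None
    spec = config.barcode_spec
    bam = config.input_bam
    if not os.path.exists(bam):
        raise ConfigurationError(f"input BAM not found: {bam}")
    with pysam.AlignmentFile(bam, "rb") as af:
        sort_order = (af.header.to_dict().get("HD") or {}).get("SO")
        regions: Optional[List[Region]] = (
            parse_regions(config.regions, af.header) if config.regions else None
        )
    if config.index and sort_order != "coordinate":
        raise ConfigurationError(
            "scBAM indexing requires a coordinate-sorted input BAM "
            f"(header SO={sort_order!r})"
        )
    bambase = bambase_of(bam)
    limit = config.limit
    batch_size = config.batch_size

    keep = config.keep_scbams
    scratch: Optional[str] = None
    if keep:
        planner = _PathPlanner(bambase, config.file_template, base_dir=None)
    else:
        scratch = config.scratch_dir or tempfile.mkdtemp(prefix="percell-")
        os.makedirs(scratch, exist_ok=True)
        planner = _PathPlanner(bambase, DEFAULT_SCBAM_TEMPLATE, base_dir=scratch)

    acceptlist = (
        read_barcode_list(config.acceptlist_path) if config.acceptlist_path else None
    )

    summary = RunSummary(scbam_dir=scratch if not keep else None)
    stats = summary.stats
    abort = threading.Event()
    futures: List[Future] = []

    def submit_batch(pool: ThreadPoolExecutor, batch: Sequence[str], paths: Dict[str, str]) -> None:
        for barcode in batch:
            path = paths.get(barcode)
            if path is None:
                summary.barcodes_skipped_empty += 1
                ev.emit("job_skipped_empty", barcode=barcode)
                continue
            job = _build_job(config, barcode, path, bambase)
            if config.fail_fast and abort.is_set():
                ev.emit("job_skipped", barcode=barcode)
                if not keep:
                    _remove_quiet(job.scbam_path)
                continue
            futures.append(pool.submit(_job_worker, job, ev, abort, config.fail_fast))

    def extract_pass(
        pass_index: int,
        batch: Sequence[str],
        classify: Optional[Callable[[Optional[str]], None]],
    ) -> Dict[str, str]:
        """Scan the input once, writing scBAMs for ``batch``.

        ``classify``, when given (first pass only), receives the extracted
        barcode of every in-region record for run-level accounting.
        """
        ev.emit("scan_start", pass_index=pass_index, batch=list(batch))
        batch_set = set(batch)
        with pysam.AlignmentFile(bam, "rb") as af:
            writers = ScbamWriterSet(af, planner.path_for)

            def on_record(rec: pysam.AlignedSegment) -> None:
                barcode = extract_barcode(rec, spec)
                if classify is not None:
                    classify(barcode)
                if barcode in batch_set:
                    writers.write(barcode, rec)

            visited, outside = scan_records(af, regions, on_record)
            if classify is not None:
                stats.outside_regions += outside
                stats.total_records += visited + outside
            if config.emit_empty:
                for barcode in batch:
                    writers.ensure_open(barcode)
            paths = writers.close()
        summary.scans += 1
        ev.emit("scan_end", pass_index=pass_index)
        return paths

    def discovery_pass() -> tuple[Dict[str, str], List[str]]:
        """First scan without an acceptance list: discover and extract.

        Assigns first-seen indices to barcodes, writes scBAMs for indices
        below the batch size, memorizes the rest for later passes.
        """
        ev.emit("scan_start", pass_index=0)
        order: List[str] = []
        index_of: Dict[str, int] = {}
        with pysam.AlignmentFile(bam, "rb") as af:
            writers = ScbamWriterSet(af, planner.path_for)

            def on_record(rec: pysam.AlignedSegment) -> None:
                barcode = extract_barcode(rec, spec)
                if barcode is None:
                    stats.unbarcoded += 1
                    return
                idx = index_of.get(barcode)
                if idx is None:
                    idx = len(order)
                    index_of[barcode] = idx
                    order.append(barcode)
                if limit is not None and idx >= limit:
                    # beyond the scBAM-count limit: treated as not accepted
                    stats.rejected_by_acceptlist += 1
                    return
                stats.assigned += 1
                stats.per_barcode[barcode] = stats.per_barcode.get(barcode, 0) + 1
                if idx < batch_size:
                    writers.write(barcode, rec)

            visited, outside = scan_records(af, regions, on_record)
            stats.outside_regions += outside
            stats.total_records += visited + outside
            paths = writers.close()
        summary.scans += 1
        ev.emit("scan_end", pass_index=0)
        return paths, order[:limit] if limit is not None else order

    fatal: Optional[str] = None
    try:
        with ThreadPoolExecutor(max_workers=config.jobs) as pool:
            try:
                if acceptlist is not None:
                    barcodes = acceptlist[:limit] if limit is not None else acceptlist
                    # plan every path up front so collisions fail before any scan
                    for barcode in barcodes:
                        planner.path_for(barcode)
                    accept_set = set(barcodes)

                    def classify(barcode: Optional[str]) -> None:
                        if barcode is None:
                            stats.unbarcoded += 1
                        elif barcode in accept_set:
                            stats.assigned += 1
                            stats.per_barcode[barcode] = (
                                stats.per_barcode.get(barcode, 0) + 1
                            )
                        else:
                            stats.rejected_by_acceptlist += 1

                    for i, batch in enumerate(plan_batches(barcodes, batch_size).batches):
                        if config.fail_fast and abort.is_set():
                            break
                        paths = extract_pass(i, batch, classify if i == 0 else None)
                        submit_batch(pool, batch, paths)
                else:
                    paths, barcodes = discovery_pass()
                    submit_batch(pool, barcodes[:batch_size], paths)
                    rest = barcodes[batch_size:]
                    if rest:
                        for k, batch in enumerate(
                            plan_batches(rest, batch_size).batches, start=1
                        ):
                            if config.fail_fast and abort.is_set():
                                break
                            paths = extract_pass(k, batch, None)
                            submit_batch(pool, batch, paths)
                summary.barcodes = list(barcodes)
            except (PercellError, OSError) as exc:
                fatal = str(exc)
                ev.emit("fatal", error=fatal)
            for future in futures:
                result = future.result()
                if result is not None:
                    summary.results.append(result)
    finally:
        ev.emit("run_end")
        if own_log:
            ev.close()
        if scratch is not None and config.scratch_dir is None:
            shutil.rmtree(scratch, ignore_errors=True)

    summary.jobs_launched = len(summary.results)
    summary.jobs_succeeded = sum(1 for r in summary.results if r.ok)
    summary.jobs_failed = summary.jobs_launched - summary.jobs_succeeded
    summary.fatal_error = fatal
    return summary
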