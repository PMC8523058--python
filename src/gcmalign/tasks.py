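"""File-based resumable task queue and the end-to-end pipeline driver.

Every expensive unit of work (subset alignment, backbone alignment, nested
recursive run) is a *task*: a small JSON record in a shared working
directory.  Claiming a task is an atomic file rename from ``tasks/pending/``
to ``tasks/running/`` — on a POSIX filesystem no two workers can win the
same rename, so any number of worker processes may share the directory.
Completed tasks move to ``tasks/done/`` and are never re-executed; a run
that crashes at any task boundary resumes exactly where it stopped, and a
worker that dies mid-task is recovered by a stale-claim timeout.

All randomness flows from a single seed through named child streams, so the
final alignment is byte-identical regardless of worker count or
interruption.

During the merge, subalignments are streamed through a single-slot
:class:`SubalignmentStore` — at most one subalignment is fully resident at
any time, bounding memory by the largest subalignment.

Workdir layout::

    workdir/
      tasks/{pending,running,done,failed}/   task records
      tasks/log.txt                          per-subset routing decisions
      subsets/                               unaligned subset FASTAs
      subalignments/                         aligned subsets
      backbones/                             backbone FASTAs
      graph/                                 edge list, clusters, trace
      nested/                                workdirs of recursive runs
      output/                                final alignment + done marker
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import multiprocessing
import os
import time
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import gcm
from .compress import compress as compress_alignment
from .backbone import builtin_progressive_align, sample_backbones
from .decompose import (
    DEFAULT_MAX_NUM_SUBSETS,
    DEFAULT_RECURSION_DEPTH_CAP,
    child_seed,
    make_plan,
    should_recurse,
)
from .guidetree import (
    build_fallback_tree,
    centroid_edge_decompose,
    parse_newick,
    random_decomposition,
)
from .msa import Alignment, Sequence, read_fasta, write_fasta

logger = logging.getLogger(__name__)

MAX_ATTEMPTS = 3
STALE_CLAIM_SECONDS = 300.0


class PipelineError(RuntimeError):
    pass


class PipelineInterrupted(RuntimeError):
    """Raised when a run stops at a task boundary (budget hook); the workdir
    is left in a consistent, resumable state."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    input: str
    workdir: str
    output: str | None = None
    tree: str = "fallback"          # strategy name or Newick path
    max_num_subsets: int = DEFAULT_MAX_NUM_SUBSETS
    recurse: bool = True
    recursion_threshold: int | None = None
    recursion_depth_cap: int = DEFAULT_RECURSION_DEPTH_CAP
    num_backbones: int = 10
    backbone_size: int = 200
    aligner: str = "builtin"        # or an external command template
    gap_open: float = -4.0
    gap_extend: float = -1.0
    seed: int = 0
    compress_threshold: int | None = None
    lossless_compress: bool = False
    workers: int = 1
    max_tasks: int | None = None    # stop after N tasks (resumability hook)
    depth: int = 0                  # internal: nesting level

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def final_output(self) -> Path:
        if self.output:
            return Path(self.output)
        return Path(self.workdir) / "output" / "final.fasta"


# ---------------------------------------------------------------------------
# Task records and queue primitives
# ---------------------------------------------------------------------------


@dataclass
class TaskRecord:
    task_id: str
    type: str  # subset_align | backbone_align | nested_run
    inputs: dict
    attempts: int = 0

    @classmethod
    def create(cls, task_type: str, inputs: dict) -> "TaskRecord":
        payload = json.dumps([task_type, inputs], sort_keys=True)
        task_id = hashlib.sha256(payload.encode()).hexdigest()[:20]
        return cls(task_id=task_id, type=task_type, inputs=inputs)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TaskRecord":
        return cls(**json.loads(text))


def _queue_dirs(workdir: Path) -> dict[str, Path]:
    return {
        state: workdir / "tasks" / state
        for state in ("pending", "running", "done", "failed")
    }


def init_workdir(workdir: str | Path) -> Path:
    workdir = Path(workdir)
    for d in _queue_dirs(workdir).values():
        d.mkdir(parents=True, exist_ok=True)
    for sub in ("subsets", "subalignments", "backbones", "graph", "output",
                "nested"):
        (workdir / sub).mkdir(exist_ok=True)
    return workdir


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_name(path.name + f".tmp{os.getpid()}")
    tmp.write_text(text)
    os.replace(tmp, path)


def enqueue(task: TaskRecord, workdir: str | Path) -> None:
    """Record a pending task; idempotent, and a no-op for done tasks."""
    dirs = _queue_dirs(Path(workdir))
    name = task.task_id + ".json"
    for state in ("done", "pending", "running"):
        if (dirs[state] / name).exists():
            return
    _atomic_write(dirs["pending"] / name, task.to_json())


def claim_next(
    workdir: str | Path,
    worker_id: str = "w0",
    stale_timeout: float = STALE_CLAIM_SECONDS,
) -> TaskRecord | None:
    """Atomically claim one pending task (rename is the lock), or None.

    Running claims older than ``stale_timeout`` seconds are pushed back to
    pending first — crash recovery for workers that died mid-task.
    """
    dirs = _queue_dirs(Path(workdir))
    now = time.time()
    for f in sorted(dirs["running"].iterdir()):
        try:
            if now - f.stat().st_mtime > stale_timeout:
                os.rename(f, dirs["pending"] / f.name)
                logger.warning("reclaimed stale task %s", f.name)
        except FileNotFoundError:
            continue
    for f in sorted(dirs["pending"].iterdir()):
        target = dirs["running"] / f.name
        try:
            os.rename(f, target)
        except FileNotFoundError:
            continue  # lost the race to another worker
        os.utime(target)
        return TaskRecord.from_json(target.read_text())
    return None


def mark_done(task: TaskRecord, workdir: str | Path) -> None:
    dirs = _queue_dirs(Path(workdir))
    name = task.task_id + ".json"
    _atomic_write(dirs["done"] / name, task.to_json())
    (dirs["running"] / name).unlink(missing_ok=True)


def mark_failed(task: TaskRecord, workdir: str | Path, error: str) -> None:
    dirs = _queue_dirs(Path(workdir))
    name = task.task_id + ".json"
    task.attempts += 1
    task.inputs = dict(task.inputs, last_error=error[-500:])
    dest = "pending" if task.attempts < MAX_ATTEMPTS else "failed"
    _atomic_write(dirs[dest] / name, task.to_json())
    (dirs["running"] / name).unlink(missing_ok=True)


def queue_counts(workdir: str | Path) -> dict[str, int]:
    return {
        state: sum(1 for _ in d.iterdir())
        for state, d in _queue_dirs(Path(workdir)).items()
    }


# ---------------------------------------------------------------------------
# Task execution
# ---------------------------------------------------------------------------


def _write_alignment_atomic(aln: Alignment, path: Path) -> None:
    tmp = path.with_name(path.name + f".tmp{os.getpid()}")
    write_fasta(aln, tmp)
    os.replace(tmp, path)


def execute_task(task: TaskRecord, workdir: str | Path) -> None:
    """Run one task to completion; outputs are written atomically."""
    if task.type in ("subset_align", "backbone_align"):
        seqs = read_fasta(task.inputs["input_fasta"], aligned=False)
        aligner_spec = task.inputs.get("aligner", "builtin")
        if aligner_spec == "builtin":
            aln = builtin_progressive_align(
                seqs,
                gap_open=task.inputs.get("gap_open", -4.0),
                gap_extend=task.inputs.get("gap_extend", -1.0),
                seed=task.inputs.get("seed", 0),
            )
        else:
            from .backbone import ExternalAlignerAdapter

            adapter = ExternalAlignerAdapter(
                name="external",
                command_template=aligner_spec,
                workdir=Path(workdir) / "tasks",
            )
            aln = adapter(seqs)
        _write_alignment_atomic(aln, Path(task.inputs["output_fasta"]))
    elif task.type == "nested_run":
        nested = PipelineConfig.from_dict(task.inputs["config"])
        run_pipeline(nested)
    else:
        raise PipelineError(f"unknown task type {task.type!r}")


def _worker_loop(workdir: str, worker_id: str, max_tasks: int | None = None) -> int:
    done = 0
    while max_tasks is None or done < max_tasks:
        task = claim_next(workdir, worker_id)
        if task is None:
            break
        try:
            execute_task(task, workdir)
        except Exception as exc:  # noqa: BLE001 - retried via the queue
            logger.warning("task %s failed: %s", task.task_id, exc)
            mark_failed(task, workdir, str(exc))
        else:
            mark_done(task, workdir)
            done += 1
    return done


def drain_queue(
    workdir: str | Path, workers: int = 1, max_tasks: int | None = None
) -> int:
    """Execute queued tasks until the queue is empty; returns tasks executed.

    With ``workers > 1``, that many processes share the queue.  The
    ``max_tasks`` budget (single-process only) stops at a task boundary and
    raises :class:`PipelineInterrupted`, leaving a resumable workdir.
    """
    workdir = Path(workdir)
    executed = 0
    if workers <= 1 or max_tasks is not None:
        executed = _worker_loop(str(workdir), "w0", max_tasks)
        counts = queue_counts(workdir)
        if max_tasks is not None and counts["pending"] > 0 and executed >= max_tasks:
            raise PipelineInterrupted(
                f"stopped after {executed} tasks; {counts['pending']} pending"
            )
    else:
        procs = [
            multiprocessing.Process(
                target=_worker_loop, args=(str(workdir), f"w{i}")
            )
            for i in range(workers)
        ]
        for p in procs:
            p.start()
        for p in procs:
            p.join()
    # Retry rounds for transiently failed tasks that went back to pending.
    for _ in range(MAX_ATTEMPTS):
        if queue_counts(workdir)["pending"] == 0:
            break
        executed += _worker_loop(str(workdir), "w-retry")
    counts = queue_counts(workdir)
    if counts["failed"]:
        failed = sorted(
            f.name for f in _queue_dirs(workdir)["failed"].iterdir()
        )
        raise PipelineError(f"tasks failed permanently: {failed}")
    return executed


# ---------------------------------------------------------------------------
# Streaming subalignment store (memory contract)
# ---------------------------------------------------------------------------


class SubalignmentStore:
    """Single-slot loader: at most one subalignment resident at a time.

    ``max_concurrent`` is the instrumented high-water mark of simultaneously
    loaded subalignments; the pipeline asserts it never exceeds 1.
    """

    def __init__(self, paths: list[Path]):
        self._paths = paths
        self._slot: tuple[int, Alignment] | None = None
        self.loads = 0
        self.concurrent = 0
        self.max_concurrent = 0

    def __len__(self) -> int:
        return len(self._paths)

    def get(self, si: int) -> Alignment:
        if self._slot is not None and self._slot[0] == si:
            return self._slot[1]
        if self._slot is not None:
            self._slot = None
            self.concurrent -= 1
        self.concurrent += 1
        self.max_concurrent = max(self.max_concurrent, self.concurrent)
        self.loads += 1
        aln = read_fasta(self._paths[si], aligned=True)
        assert isinstance(aln, Alignment)
        self._slot = (si, aln)
        return aln


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _log_task(workdir: Path, message: str) -> None:
    with open(workdir / "tasks" / "log.txt", "a") as fh:
        fh.write(message + "\n")


def _decompose(
    config: PipelineConfig, sequences: list[Sequence], target_size: int
) -> list[list[str]]:
    ids = [s.id for s in sequences]
    cache = Path(config.workdir) / "subsets" / "decomposition.json"
    if cache.exists():
        return json.loads(cache.read_text())
    if config.tree == "random":
        result = random_decomposition(ids, target_size, seed=config.seed)
    else:
        if config.tree in ("fallback", ""):
            tree = build_fallback_tree(sequences, seed=config.seed)
        else:
            tree = parse_newick(Path(config.tree))
            if set(tree.leaf_labels()) != set(ids):
                raise PipelineError(
                    "guide tree leaves do not match the input sequence ids"
                )
        result = centroid_edge_decompose(tree, target_size)
    _atomic_write(cache, json.dumps(result.subsets, indent=1))
    return result.subsets


def run_pipeline(config: PipelineConfig) -> Path:
    """Run (or resume) the full divide–align–merge pipeline; returns the
    final alignment path.  Re-invoking on a completed workdir is a no-op."""
    workdir = init_workdir(config.workdir)
    final = config.final_output()
    marker = workdir / "output" / "done.json"
    if marker.exists() and final.exists():
        logger.info("workdir already complete: %s", final)
        return final

    sequences = read_fasta(config.input, aligned=False)
    assert isinstance(sequences, list)
    n = len(sequences)
    by_id = {s.id: s for s in sequences}
    plan = make_plan(
        n,
        max_num_subsets=config.max_num_subsets,
        backbone_size=config.backbone_size,
        user_threshold=config.recursion_threshold,
        recurse_enabled=config.recurse,
    )
    subsets = _decompose(config, sequences, plan.target_subset_size)

    # ---- subset alignment (direct or recursive) --------------------------
    sub_paths: list[Path] = []
    for i, subset in enumerate(subsets):
        unaligned = workdir / "subsets" / f"subset_{i:04d}.fasta"
        aligned = workdir / "subalignments" / f"sub_{i:04d}.fasta"
        sub_paths.append(aligned)
        if not unaligned.exists():
            tmp = unaligned.with_suffix(".tmp")
            write_fasta([by_id[r] for r in subset], tmp)
            os.replace(tmp, unaligned)
        recurse_here = (
            should_recurse(len(subset), plan)
            and config.depth < config.recursion_depth_cap
            and len(subset) < n
        )
        if recurse_here:
            nested_cfg = dataclasses.replace(
                config,
                input=str(unaligned),
                workdir=str(workdir / "nested" / f"sub_{i:04d}"),
                output=str(aligned),
                seed=child_seed(config.seed, i),
                workers=1,
                max_tasks=None,
                depth=config.depth + 1,
            )
            task = TaskRecord.create(
                "nested_run", {"config": nested_cfg.to_dict()}
            )
        else:
            task = TaskRecord.create(
                "subset_align",
                {
                    "input_fasta": str(unaligned),
                    "output_fasta": str(aligned),
                    "seed": child_seed(config.seed, i),
                    "aligner": config.aligner,
                    "gap_open": config.gap_open,
                    "gap_extend": config.gap_extend,
                },
            )
        if not (workdir / "tasks" / "done" / (task.task_id + ".json")).exists():
            _log_task(
                workdir,
                f"subset {i} size {len(subset)} -> {task.type}",
            )
        enqueue(task, workdir)
    drain_queue(workdir, config.workers, config.max_tasks)

    if len(subsets) == 1:
        aln = read_fasta(sub_paths[0], aligned=True)
        return _finalize(config, aln, {"n": n, "subsets": 1})

    # ---- backbones -------------------------------------------------------
    samples = sample_backbones(
        subsets,
        num_backbones=config.num_backbones,
        backbone_size=config.backbone_size,
        seed=child_seed(config.seed, 10_001),
    )
    bb_aligned: list[Path] = []
    for bi, sample in enumerate(samples):
        unaligned = workdir / "backbones" / f"backbone_{bi:03d}.fasta"
        aligned = workdir / "backbones" / f"backbone_{bi:03d}.aligned.fasta"
        bb_aligned.append(aligned)
        if not unaligned.exists():
            tmp = unaligned.with_suffix(".tmp")
            write_fasta([by_id[r] for r in sample.row_ids()], tmp)
            os.replace(tmp, unaligned)
        task = TaskRecord.create(
            "backbone_align",
            {
                "input_fasta": str(unaligned),
                "output_fasta": str(aligned),
                "seed": child_seed(config.seed, 20_001 + bi),
                "aligner": config.aligner,
                "gap_open": config.gap_open,
                "gap_extend": config.gap_extend,
            },
        )
        enqueue(task, workdir)
    drain_queue(workdir, config.workers, config.max_tasks)

    # ---- merge (streaming: one subalignment resident at a time) ----------
    backbones = []
    for p in bb_aligned:
        aln = read_fasta(p, aligned=True)
        assert isinstance(aln, Alignment)
        backbones.append(aln)
    backbone_rows = {rid for b in backbones for rid in b.row_ids}
    store = SubalignmentStore(sub_paths)
    column_counts: list[int] = []
    home: dict[str, tuple[int, list[int]]] = {}
    for si in range(len(store)):
        sub = store.get(si)
        column_counts.append(sub.length)
        for rid in sub.row_ids:
            if rid in backbone_rows:
                home[rid] = (si, sub.site_to_column(rid))
    graph = gcm.build_graph_from_maps(column_counts, home, backbones)
    gcm.write_graph(graph, workdir / "graph" / "graph.txt")
    clusters = gcm.mcl_cluster(graph)
    clusters = gcm.enforce_cluster_validity(clusters, graph)
    gcm.write_clusters(clusters, workdir / "graph" / "clusters.txt")
    trace = gcm.order_clusters(clusters, graph)
    gcm.write_clusters(
        [set(c.items()) for c in trace.clusters],
        workdir / "graph" / "trace.txt",
    )

    tmp_final = final.with_name(final.name + ".tmp")
    final.parent.mkdir(parents=True, exist_ok=True)
    with open(tmp_final, "w") as fh:
        for rid, row in gcm.iter_merged_rows(trace, store.get, len(store)):
            fh.write(f">{rid}\n")
            for k in range(0, len(row), 60):
                fh.write(row[k : k + 60] + "\n")
    os.replace(tmp_final, final)
    if store.max_concurrent > 1:
        raise PipelineError(
            f"memory contract violated: {store.max_concurrent} subalignments "
            "were loaded simultaneously"
        )

    merged = read_fasta(final, aligned=True)
    assert isinstance(merged, Alignment)
    stats = {
        "n": n,
        "subsets": len(subsets),
        "backbones": len(backbones),
        "columns": merged.length,
        "max_concurrent_subalignments": store.max_concurrent,
    }
    return _finalize(config, merged, stats)


def _finalize(config: PipelineConfig, aln: Alignment, stats: dict) -> Path:
    workdir = Path(config.workdir)
    final = config.final_output()
    final.parent.mkdir(parents=True, exist_ok=True)
    if config.compress_threshold is not None:
        aln, report = compress_alignment(
            aln, config.compress_threshold, config.lossless_compress
        )
        stats["compression"] = dataclasses.asdict(report)
    _write_alignment_atomic(aln, final)
    _atomic_write(
        workdir / "output" / "done.json",
        json.dumps({"output": str(final), **stats}, indent=1, sort_keys=True),
    )
    return final
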