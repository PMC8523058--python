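"""Task queue semantics, concurrency, resumability, pipeline orchestration."""

import json
import os
import threading
import time
from pathlib import Path

import pytest

from gcmalign.msa import read_fasta, write_fasta, assert_letters_conserved
from gcmalign.simulate import SimConfig, simulate
from gcmalign.tasks import (
    PipelineConfig,
    PipelineInterrupted,
    TaskRecord,
    claim_next,
    drain_queue,
    enqueue,
    init_workdir,
    mark_done,
    queue_counts,
    run_pipeline,
)


def make_task(i):
    return TaskRecord.create("subset_align", {"i": i})


class TestQueue:
    def test_enqueue_idempotent(self, tmp_path):
        wd = init_workdir(tmp_path)
        t = make_task(1)
        enqueue(t, wd)
        enqueue(t, wd)
        assert queue_counts(wd)["pending"] == 1

    def test_enqueue_after_done_is_noop(self, tmp_path):
        wd = init_workdir(tmp_path)
        t = make_task(1)
        enqueue(t, wd)
        claimed = claim_next(wd)
        mark_done(claimed, wd)
        enqueue(make_task(1), wd)
        counts = queue_counts(wd)
        assert counts["pending"] == 0 and counts["done"] == 1

    def test_many_enqueues_distinct(self, tmp_path):
        wd = init_workdir(tmp_path)
        for i in range(100):
            enqueue(make_task(i), wd)
        assert queue_counts(wd)["pending"] == 100

    def test_claim_empty_returns_none(self, tmp_path):
        wd = init_workdir(tmp_path)
        assert claim_next(wd) is None

    def test_concurrent_claims_disjoint(self, tmp_path):
        for rep in range(20):
            wd = init_workdir(tmp_path / f"rep{rep}")
            tasks = [make_task(i) for i in range(10)]
            for t in tasks:
                enqueue(t, wd)
            claimed = {0: [], 1: []}

            def worker(k):
                while True:
                    t = claim_next(wd, worker_id=f"w{k}")
                    if t is None:
                        return
                    claimed[k].append(t.task_id)

            threads = [threading.Thread(target=worker, args=(k,))
                       for k in range(2)]
            for th in threads:
                th.start()
            for th in threads:
                th.join()
            ids0, ids1 = set(claimed[0]), set(claimed[1])
            assert not ids0 & ids1
            assert ids0 | ids1 == {t.task_id for t in tasks}

    def test_stale_running_task_reclaimed(self, tmp_path):
        wd = init_workdir(tmp_path)
        t = make_task(1)
        enqueue(t, wd)
        claimed = claim_next(wd)
        assert claimed is not None
        # simulate a worker that died mid-task: age the running claim
        running = wd / "tasks" / "running" / (t.task_id + ".json")
        old = time.time() - 10_000
        os.utime(running, (old, old))
        reclaimed = claim_next(wd, worker_id="w2", stale_timeout=60)
        assert reclaimed is not None and reclaimed.task_id == t.task_id


@pytest.fixture(scope="module")
def small_dataset(tmp_path_factory):
    d = tmp_path_factory.mktemp("data")
    true_aln, seqs, _ = simulate(
        SimConfig(n_taxa=30, seed=13, substitution_rate=0.2)
    )
    fasta = d / "in.fasta"
    write_fasta(seqs, fasta)
    return fasta, seqs, true_aln


def small_config(fasta, workdir, **kw):
    defaults = dict(
        input=str(fasta), workdir=str(workdir), seed=3,
        max_num_subsets=5, num_backbones=3, backbone_size=15,
    )
    defaults.update(kw)
    return PipelineConfig(**defaults)


class TestPipeline:
    def test_run_produces_conserving_alignment(self, small_dataset, tmp_path):
        fasta, seqs, _ = small_dataset
        out = run_pipeline(small_config(fasta, tmp_path / "wd"))
        aln = read_fasta(out, aligned=True)
        assert_letters_conserved(aln, seqs)

    def test_rerun_is_noop(self, small_dataset, tmp_path):
        fasta, _, _ = small_dataset
        cfg = small_config(fasta, tmp_path / "wd")
        out1 = run_pipeline(cfg)
        content = out1.read_bytes()
        mtimes = {
            f.name: f.stat().st_mtime_ns
            for f in (tmp_path / "wd" / "tasks" / "done").iterdir()
        }
        out2 = run_pipeline(cfg)
        assert out2.read_bytes() == content
        mtimes2 = {
            f.name: f.stat().st_mtime_ns
            for f in (tmp_path / "wd" / "tasks" / "done").iterdir()
        }
        assert mtimes2 == mtimes  # zero tasks re-executed

    def test_worker_count_does_not_change_output(self, small_dataset,
                                                 tmp_path):
        fasta, _, _ = small_dataset
        out1 = run_pipeline(small_config(fasta, tmp_path / "w1", workers=1))
        out4 = run_pipeline(small_config(fasta, tmp_path / "w4", workers=4))
        assert out1.read_bytes() == out4.read_bytes()

    def test_interrupt_and_resume_identical(self, small_dataset, tmp_path):
        fasta, _, _ = small_dataset
        ref = run_pipeline(small_config(fasta, tmp_path / "ref"))
        cfg = small_config(fasta, tmp_path / "resume", max_tasks=2)
        with pytest.raises(PipelineInterrupted):
            run_pipeline(cfg)
        cfg2 = small_config(fasta, tmp_path / "resume")
        out = run_pipeline(cfg2)
        assert out.read_bytes() == ref.read_bytes()

    def test_memory_contract_single_subalignment(self, small_dataset,
                                                 tmp_path):
        fasta, _, _ = small_dataset
        out = run_pipeline(small_config(fasta, tmp_path / "mem"))
        stats = json.loads(
            (tmp_path / "mem" / "output" / "done.json").read_text()
        )
        assert stats["max_concurrent_subalignments"] == 1
        assert stats["subsets"] >= 5

    def test_user_supplied_guide_tree(self, small_dataset, tmp_path):
        fasta, seqs, _ = small_dataset
        from gcmalign.guidetree import build_fallback_tree, write_newick

        tree = build_fallback_tree(seqs, seed=0)
        nwk = tmp_path / "guide.nwk"
        write_newick(tree, nwk)
        cfg = small_config(fasta, tmp_path / "usertree", tree=str(nwk))
        out = run_pipeline(cfg)
        aln = read_fasta(out, aligned=True)
        assert_letters_conserved(aln, seqs)

    def test_random_decomposition_strategy(self, small_dataset, tmp_path):
        fasta, seqs, _ = small_dataset
        cfg = small_config(fasta, tmp_path / "rand", tree="random")
        out = run_pipeline(cfg)
        aln = read_fasta(out, aligned=True)
        assert_letters_conserved(aln, seqs)

    def test_compression_in_pipeline(self, small_dataset, tmp_path):
        fasta, seqs, _ = small_dataset
        cfg = small_config(
            fasta, tmp_path / "comp", compress_threshold=1,
            lossless_compress=True,
        )
        out = run_pipeline(cfg)
        aln = read_fasta(out, aligned=True)
        assert_letters_conserved(aln, seqs)
        stats = json.loads(
            (tmp_path / "comp" / "output" / "done.json").read_text()
        )
        assert stats["compression"]["pairs_lost"] == 0
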