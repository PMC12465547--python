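"""End-to-end orchestration: BAM pipeline runs and the simulated benchmark.

``run_pipeline`` drives split -> align -> call -> filter for a barcoded BAM
with a single pooled error-model fit across cell types. ``run_sim_benchmark``
reproduces the simulated evaluation design: 100 deletions on a circular
reference, the top ``n_true`` by junction support as truths, per-truth
datasets of deletion + wild-type + shared structured-noise reads,
downsampled to coverage tiers and scored with breakpoint tolerance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import align as _align
from . import caller as _caller
from . import errormodel as _em
from . import benchmark as _bm
from .io import (
    ReferenceGenome,
    read_cell_annotation,
    read_fasta,
    write_call_table,
)
from .pooling import (
    DEFAULT_BARCODE_TAG,
    DEFAULT_MAX_CELLS,
    POLICY_MITO_AND_UNMAPPED,
    split_bam_by_cell_type,
    subsample_barcodes,
)
from .simulate import (
    SimConfig,
    TruthRecord,
    _GenomeSampler,
    _position_weights,
    gene_id_array,
    genome_weights_for_deletion,
    junction_covering_starts,
    junction_position,
    make_deletion_genome,
    mat_to_reads,
    random_gene_weights,
    sample_deletions,
    sample_starts,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of a BAM pipeline run (defaults per module contracts)."""

    bam: str
    annotation: str
    reference: str
    outdir: str
    barcode_tag: str = DEFAULT_BARCODE_TAG
    read_policy: str = POLICY_MITO_AND_UNMAPPED
    mito_contig: Optional[str] = None
    max_cells: int = DEFAULT_MAX_CELLS
    seed: int = 0
    k: int = _align.DEFAULT_K
    min_anchor: int = _align.DEFAULT_MIN_ANCHOR
    min_del_len: int = _align.DEFAULT_MIN_DEL_LEN
    anchor: int = _caller.DEFAULT_WT_ANCHOR
    noise_threshold: float = _em.DEFAULT_NOISE_THRESHOLD
    fdr: float = _em.DEFAULT_FDR
    min_support: int = _em.DEFAULT_MIN_SUPPORT
    min_wildtype: int = _em.DEFAULT_MIN_WILDTYPE


def _analyze_pool(
    index: _align.SeedIndex,
    reads: Sequence[tuple[str, str]],
    cell_type: str,
    min_anchor: int,
    min_del_len: int,
    anchor: int,
) -> tuple[list[_caller.DeletionCandidate], dict]:
    """Align one read pool and produce raw candidates with s, w, f."""
    alignments = _align.align_reads(
        index, reads, min_anchor=min_anchor, min_del_len=min_del_len
    )
    tallies = _align.classify_reads(alignments)
    candidates = _caller.call_candidates(
        alignments,
        index.L,
        min_del_len=min_del_len,
        anchor=anchor,
        cell_type=cell_type,
    )
    return candidates, tallies


def _filter_pooled(
    candidates: list[_caller.DeletionCandidate],
    config_like,
) -> tuple[list[_caller.DeletionCandidate], Optional[_em.ErrorModel], bool]:
    """Single pooled error-model fit + filtering across cell types.

    When the sub-threshold noise stratum is too small to fit the
    beta-binomial (shallow inputs), a conservative binomial null at the
    midpoint of the artifact band (p = noise_threshold / 2) is used
    instead, so candidates are still tested rather than passed or dropped
    wholesale; the degradation is logged.
    """
    try:
        passing, model = _em.filter_calls(
            candidates,
            fdr=config_like.fdr,
            noise_threshold=config_like.noise_threshold,
            min_support=config_like.min_support,
            min_wildtype=config_like.min_wildtype,
        )
        return passing, model, False
    except _em.ModelFitError as exc:
        logger.warning(
            "background model unfittable (%s); falling back to a binomial "
            "null at p = %.4g", exc, config_like.noise_threshold / 2,
        )
        model = _em.ErrorModel(
            alpha=float("nan"), beta=float("nan"),
            mu=config_like.noise_threshold / 2, sigma2=0.0,
            n_noise=0, fallback=True,
        )
        passing, model = _em.filter_calls(
            candidates,
            model=model,
            fdr=config_like.fdr,
            noise_threshold=config_like.noise_threshold,
            min_support=config_like.min_support,
            min_wildtype=config_like.min_wildtype,
        )
        return passing, model, True


def run_pipeline(config: RunConfig) -> dict:
    """Full BAM pipeline; writes per-cell-type and merged call tables plus
    a manifest, and returns a summary dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = read_fasta(config.reference)
    annotation = read_cell_annotation(config.annotation)
    annotation = subsample_barcodes(annotation, config.max_cells, config.seed)
    pools, pool_tallies = split_bam_by_cell_type(
        config.bam,
        annotation,
        barcode_tag=config.barcode_tag,
        read_policy=config.read_policy,
        mito_contig=config.mito_contig,
    )
    if pool_tallies["pooled"] == 0:
        raise ValueError("no reads pooled: annotation does not overlap the BAM")
    index = _align.build_seed_index(ref, config.k)
    all_candidates: list[_caller.DeletionCandidate] = []
    read_tallies: dict[str, dict] = {}
    for label, pool in pools.items():
        reads = [(r.name, r.sequence.upper()) for r in pool.reads]
        cands, tallies = _analyze_pool(
            index, reads, label, config.min_anchor, config.min_del_len, config.anchor
        )
        read_tallies[label] = tallies
        all_candidates.extend(cands)
    passing, model, unfitted = _filter_pooled(all_candidates, config)
    # deterministic table order
    all_candidates.sort(key=lambda c: (c.cell_type, c.del_start, c.del_end))
    merged_path = outdir / "calls_merged.tsv"
    write_call_table(all_candidates, merged_path)
    per_type_paths = {}
    for label in pools:
        path = outdir / f"calls_{label}.tsv"
        write_call_table([c for c in all_candidates if c.cell_type == label], path)
        per_type_paths[label] = str(path)
    manifest = {
        "parameters": asdict(config),
        "reference": {"name": ref.name, "length": ref.length},
        "pool_tallies": pool_tallies,
        "read_tallies": read_tallies,
        "n_raw_candidates": len(all_candidates),
        "n_noise": model.n_noise if model else 0,
        "n_tested": sum(1 for c in all_candidates if c.p is not None),
        "n_pass": len(passing),
        "model": (
            {
                "alpha": model.alpha, "beta": model.beta,
                "mu": model.mu, "sigma2": model.sigma2,
                "fallback": model.fallback,
            }
            if model
            else None
        ),
        "model_unfitted": unfitted,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "candidates": all_candidates,
        "passing": passing,
        "model": model,
        "manifest": manifest,
        "merged_table": str(merged_path),
        "per_type_tables": per_type_paths,
    }


# --- simulated benchmark -------------------------------------------------------


@dataclass
class TierMetrics:
    tier: int
    result: _bm.BenchmarkResult
    n_datasets: int
    n_calls: int


@dataclass
class SimBenchmarkRun:
    truths: list[TruthRecord]
    per_tier: dict[int, TierMetrics] = field(default_factory=dict)


class _FilterParams:
    def __init__(self, fdr, noise_threshold, min_support, min_wildtype):
        self.fdr = fdr
        self.noise_threshold = noise_threshold
        self.min_support = min_support
        self.min_wildtype = min_wildtype


def run_sim_benchmark(
    config: SimConfig,
    tiers: Optional[Sequence[int]] = None,
    tolerance_bp: int = _bm.DEFAULT_TOLERANCE_BP,
    min_anchor: int = _align.DEFAULT_MIN_ANCHOR,
    min_del_len: int = _align.DEFAULT_MIN_DEL_LEN,
    fdr: float = _em.DEFAULT_FDR,
) -> SimBenchmarkRun:
    """Simulate the benchmark and score the pipeline on it.

    For each of the ``n_true`` highest junction-support deletions an
    evaluation dataset is formed from its ``n_del_reads`` deletion-derived
    reads, ``n_wt_reads`` wild-type reads and the shared ``n_noise_reads``
    noise pool built from the remaining deletions, then downsampled to
    each coverage tier (component counts follow the exact multivariate
    hypergeometric law of uniform downsampling, so only surviving reads
    are materialized). Per tier, confusion counts are pooled over the
    datasets (each contributes its own truth).
    """
    ref = config.ref
    L = ref.length
    rl = config.read_length
    tiers = list(tiers if tiers is not None else config.coverage_tiers)
    ss = np.random.SeedSequence(config.seed)
    rng_del, rng_pools, rng_noise, rng_ds, rng_err = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    deletions = sample_deletions(
        ref, config.deletion_lengths, config.per_length, rng_del
    )
    n_genomes = len(deletions)
    genomes = [make_deletion_genome(ref, s, e) for s, e in deletions]
    samplers = [_GenomeSampler(g, rl) for g in genomes]
    wt_sampler = _GenomeSampler(ref.sequence, rl)
    # positional coverage profile: transcript-weighted by default
    if isinstance(config.gene_weights, str) and config.gene_weights == "auto":
        profile = random_gene_weights(L, rng_del)
    else:
        profile = config.gene_weights
    ref_w = _position_weights(L, profile)
    if profile is None:
        gene_id = None
    else:
        intervals = profile.genes if hasattr(profile, "genes") else list(profile)
        gene_id = gene_id_array(L, intervals)
    floor = float(ref_w.min()) if ref_w is not None else 0.0
    # per-genome simulated read pools (start positions; strands drawn at
    # materialization) and their junction support
    starts_pool = [
        sample_starts(
            len(genomes[i]),
            config.n_del_reads,
            rng_pools,
            genome_weights_for_deletion(
                ref_w, gene_id, *deletions[i], L, rl,
                config.readthrough_fraction, floor,
            ),
        )
        for i in range(n_genomes)
    ]
    support = np.array(
        [
            int(
                junction_covering_starts(
                    starts_pool[i],
                    junction_position(*deletions[i], L),
                    len(genomes[i]),
                    rl,
                    min_anchor,
                ).sum()
            )
            for i in range(n_genomes)
        ]
    )
    order = np.argsort(-support, kind="stable")
    true_idx = list(map(int, order[: config.n_true]))
    noise_idx = list(map(int, order[config.n_true :]))

    nominal_h = config.n_del_reads / max(1, config.n_del_reads + config.n_wt_reads)
    truths = [
        TruthRecord(
            del_start=deletions[i][0],
            del_end=deletions[i][1],
            crosses_origin=deletions[i][0] > deletions[i][1],
            target_heteroplasmy=nominal_h,
            role="true_deletion",
        )
        for i in true_idx
    ] + [
        TruthRecord(
            del_start=deletions[i][0],
            del_end=deletions[i][1],
            crosses_origin=deletions[i][0] > deletions[i][1],
            target_heteroplasmy=0.0,
            role="noise",
        )
        for i in noise_idx
    ]

    # shared noise pool: the noise genomes' pools merged and downsampled
    # (multivariate hypergeometric == uniform without replacement)
    if noise_idx and config.n_noise_reads:
        noise_counts = rng_noise.multivariate_hypergeometric(
            [config.n_del_reads] * len(noise_idx), config.n_noise_reads
        )
        ng_ids, ng_starts = [], []
        for gi, cnt in zip(noise_idx, noise_counts):
            if cnt == 0:
                continue
            sel = rng_noise.choice(config.n_del_reads, size=cnt, replace=False)
            ng_ids.append(np.full(cnt, gi, dtype=np.int64))
            ng_starts.append(starts_pool[gi][sel])
        noise_gid = np.concatenate(ng_ids) if ng_ids else np.empty(0, dtype=np.int64)
        noise_start = np.concatenate(ng_starts) if ng_starts else np.empty(0, dtype=np.int64)
    else:
        noise_gid = np.empty(0, dtype=np.int64)
        noise_start = np.empty(0, dtype=np.int64)

    index = _align.build_seed_index(ref, _align.DEFAULT_K)
    fparams = _FilterParams(fdr, _em.DEFAULT_NOISE_THRESHOLD,
                            _em.DEFAULT_MIN_SUPPORT, _em.DEFAULT_MIN_WILDTYPE)
    run = SimBenchmarkRun(truths=truths)
    pool_sizes = [config.n_del_reads, config.n_wt_reads, len(noise_gid)]

    for tier in tiers:
        tier = int(tier)
        tp = fp = fn = 0
        n_calls = 0
        maes: list[float] = []
        per_dataset: list[list[_caller.DeletionCandidate]] = []
        for di, gi in enumerate(true_idx):
            counts = rng_ds.multivariate_hypergeometric(pool_sizes, tier)
            c_del, c_wt, c_noise = map(int, counts)
            reads: list[tuple[str, str]] = []
            if c_del:
                sel = rng_ds.choice(config.n_del_reads, size=c_del, replace=False)
                mat = samplers[gi].materialize(
                    starts_pool[gi][sel],
                    rng_ds.random(c_del) < 0.5,
                    config.error_rate,
                    rng_err,
                )
                reads += mat_to_reads(mat, f"d{di}")
            if c_wt:
                mat = wt_sampler.materialize(
                    sample_starts(L, c_wt, rng_ds, ref_w),
                    rng_ds.random(c_wt) < 0.5,
                    config.error_rate,
                    rng_err,
                )
                reads += mat_to_reads(mat, f"w{di}")
            if c_noise:
                sel = rng_ds.choice(len(noise_gid), size=c_noise, replace=False)
                for k, (ngi, cnt) in enumerate(
                    zip(*np.unique(noise_gid[sel], return_counts=True))
                ):
                    mask = noise_gid[sel] == ngi
                    mat = samplers[int(ngi)].materialize(
                        noise_start[sel][mask],
                        rng_ds.random(int(cnt)) < 0.5,
                        config.error_rate,
                        rng_err,
                    )
                    reads += mat_to_reads(mat, f"n{di}g{ngi}")
            candidates, _ = _analyze_pool(
                index, reads, f"dataset{di}", min_anchor, min_del_len, min_anchor
            )
            per_dataset.append(candidates)
        # one pooled error-model fit and one BH pass across the datasets of
        # the run: a single dataset's noise stratum is too small to fit (and
        # its tested set too small for meaningful multiplicity correction),
        # mirroring the single per-sample fit across cell types
        pooled = [c for cands in per_dataset for c in cands]
        _filter_pooled(pooled, fparams)
        for di, candidates in enumerate(per_dataset):
            calls = [c for c in candidates if c.passed]
            res = _bm.score_calls(
                calls, [truths[di]], tolerance_bp, L,
                truth_heteroplasmy=[truths[di].target_heteroplasmy],
            )
            tp += res.tp
            fp += res.fp
            fn += res.fn
            n_calls += len(calls)
            if res.heteroplasmy_mae is not None:
                maes.append(res.heteroplasmy_mae)
        result = _bm.compute_metrics(
            tp, fp, fn,
            heteroplasmy_mae=(sum(maes) / len(maes)) if maes else None,
        )
        run.per_tier[tier] = TierMetrics(
            tier=tier, result=result, n_datasets=len(true_idx), n_calls=n_calls
        )
        logger.info(
            "tier %d: tp=%d fp=%d fn=%d precision=%.3f recall=%.3f f1=%.3f",
            tier, tp, fp, fn, result.precision, result.recall, result.f1,
        )
    return run
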