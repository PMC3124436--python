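"""End-to-end orchestration of the five prediction variants.

The five variants share two trained paths: STR (spatial-window RBF-SVM on
the combined profile + RASA + depth + protrusion descriptors) and SEQ
(sliding-window RBF-SVM on the scaled profile).  ``STR_RFP`` is STR
followed by the spatial false-positive filter; the ensemble variants AND
the (optionally filtered) structure calls with the sequence calls.  All
variants evaluated in one run share the same chain-level fold plan and
the same balanced negative samples, so their metrics are directly
comparable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from hemebind.classify import (
    ChainBundle,
    CrossValResult,
    PredictionTrack,
    TrainConfig,
    cross_validate,
)
from hemebind.encoding import (
    DEFAULT_SLIDING_WINDOW,
    DEFAULT_SPATIAL_WINDOW,
    FeatureMask,
)
from hemebind.evaluation import Metrics, compute_metrics, confusion, fold_average
from hemebind.geometry import geometry_blocks
from hemebind.labeling import DEFAULT_CONTACT_CUTOFF, label_binding_residues
from hemebind.postprocess import FilterParams, filter_false_positives, vote_combine
from hemebind.pssm import parse_pssm, scale_pssm
from hemebind.structure import parse_structure

__all__ = [
    "VARIANTS",
    "PipelineConfig",
    "VariantResult",
    "RunManifest",
    "load_benchmark",
    "run_variant",
    "run_all_variants",
]

VARIANTS = ("STR", "STR_RFP", "SEQ", "STR+SEQ", "STR_RFP+SEQ")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of one cross-validated run."""

    m: int = DEFAULT_SPATIAL_WINDOW
    n: int = DEFAULT_SLIDING_WINDOW
    mask: FeatureMask = field(default_factory=FeatureMask)
    filter_params: FilterParams = field(default_factory=FilterParams)
    c_grid: tuple | None = None
    gamma_grid: tuple | None = None
    n_folds: int = 5
    fold_seed: int = 0
    sample_seed: int = 0
    grid_seed: int = 0

    def train_config(self, path: str) -> TrainConfig:
        kwargs = dict(
            path=path,
            m=self.m,
            n=self.n,
            mask=self.mask,
            n_folds=self.n_folds,
            fold_seed=self.fold_seed,
            sample_seed=self.sample_seed,
            grid_seed=self.grid_seed,
        )
        if self.c_grid is not None:
            kwargs["c_grid"] = tuple(self.c_grid)
        if self.gamma_grid is not None:
            kwargs["gamma_grid"] = tuple(self.gamma_grid)
        return TrainConfig(**kwargs)


@dataclass
class VariantResult:
    variant: str
    per_fold: list[Metrics]
    mean: Metrics
    tracks: dict[str, PredictionTrack]


@dataclass
class RunManifest:
    """Provenance of one pipeline run: config, seeds, inputs, timings."""

    config: dict
    input_hashes: dict[str, str]
    timings_s: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "input_hashes": self.input_hashes,
                "timings_s": self.timings_s,
                "outputs": self.outputs,
            },
            indent=2,
            sort_keys=True,
        )


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def load_benchmark(
    data_dir: str | Path,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    need_pssm: bool = True,
    sasa_points: int = 960,
) -> list[ChainBundle]:
    """Load a benchmark directory of per-chain PDB (+ optional PSSM) files.

    Labels are derived from heme contacts in each PDB; geometry blocks are
    computed on the unbound chain.  A PSSM, when present, must have one
    row per chain residue (no alignment heuristics are attempted).
    """
    data_dir = Path(data_dir)
    pdbs = sorted(data_dir.glob("*.pdb"))
    if not pdbs:
        raise ConfigurationError(f"no PDB files in {data_dir}")
    bundles = []
    for pdb_path in pdbs:
        chains, hemes = parse_structure(pdb_path.read_text())
        if len(chains) != 1:
            raise ConfigurationError(f"{pdb_path.name}: expected a single chain")
        chain = chains[0]
        labeled = label_binding_residues(chain, hemes, cutoff=cutoff)
        geometry = geometry_blocks(chain, n_points=sasa_points)
        profile = None
        pssm_path = pdb_path.with_suffix(".pssm")
        if pssm_path.exists():
            pssm = parse_pssm(pssm_path.read_text())
            if pssm.length != len(chain.residues):
                raise ConfigurationError(
                    f"{pssm_path.name}: {pssm.length} profile rows for "
                    f"{len(chain.residues)} residues"
                )
            profile = scale_pssm(pssm)
        elif need_pssm:
            raise ConfigurationError(f"missing PSSM for {pdb_path.name}")
        bundles.append(
            ChainBundle(key=pdb_path.stem, labeled=labeled, profile=profile, geometry=geometry)
        )
    return bundles


def _variant_needs(variant: str) -> tuple[bool, bool, bool]:
    """(needs structure path, needs sequence path, applies filter)."""
    if variant not in VARIANTS:
        raise ConfigurationError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    needs_str = variant != "SEQ"
    needs_seq = "SEQ" in variant
    filtered = "RFP" in variant
    return needs_str, needs_seq, filtered


def _fold_metrics(
    plan_folds: list[list[str]],
    tracks: dict[str, PredictionTrack],
    by_key: dict[str, ChainBundle],
) -> list[Metrics]:
    out = []
    for test_keys in plan_folds:
        preds, truths = [], []
        for key in test_keys:
            tr = tracks[key]
            preds.append(tr.calls[tr.scored])
            truths.append(by_key[key].labeled.labels[tr.scored])
        out.append(compute_metrics(confusion(np.concatenate(preds), np.concatenate(truths))))
    return out


def run_all_variants(
    dataset: list[ChainBundle],
    config: PipelineConfig = PipelineConfig(),
    variants: tuple[str, ...] = VARIANTS,
) -> dict[str, VariantResult]:
    """Cross-validate the requested variants with shared folds and models.

    The structure and sequence SVMs are each trained once per fold; the
    filter and the vote are pure post-processing of their tracks.
    """
    needs_str = any(_variant_needs(v)[0] for v in variants)
    needs_seq = any(_variant_needs(v)[1] for v in variants)
    needs_filter = any(_variant_needs(v)[2] for v in variants)
    if (needs_seq or config.mask.pssm) and any(b.profile is None for b in dataset):
        raise ConfigurationError("a PSSM-dependent variant needs a profile for every chain")

    by_key = {b.key: b for b in dataset}
    str_cv: CrossValResult | None = None
    seq_cv: CrossValResult | None = None
    if needs_str:
        str_cv = cross_validate(dataset, config.train_config("structure"))
    if needs_seq:
        seq_cv = cross_validate(dataset, config.train_config("sequence_pssm"))
    plan = (str_cv or seq_cv).plan

    filtered_tracks: dict[str, PredictionTrack] = {}
    if needs_filter:
        for key, track in str_cv.tracks.items():
            filtered_tracks[key] = filter_false_positives(
                track, by_key[key].chain, config.filter_params
            )

    results: dict[str, VariantResult] = {}
    for variant in variants:
        v_str, v_seq, v_filt = _variant_needs(variant)
        if variant == "SEQ":
            tracks = seq_cv.tracks
        elif not v_seq:
            tracks = filtered_tracks if v_filt else str_cv.tracks
        else:
            left = filtered_tracks if v_filt else str_cv.tracks
            tracks = {
                key: vote_combine(left[key], seq_cv.tracks[key]) for key in left
            }
        per_fold = _fold_metrics(plan.folds, tracks, by_key)
        results[variant] = VariantResult(
            variant=variant,
            per_fold=per_fold,
            mean=fold_average(per_fold),
            tracks=tracks,
        )
    return results


def run_variant(
    dataset: list[ChainBundle],
    variant: str,
    config: PipelineConfig = PipelineConfig(),
) -> VariantResult:
    """Cross-validate a single prediction variant."""
    return run_all_variants(dataset, config, variants=(variant,))[variant]


def metrics_report(results: dict[str, VariantResult]) -> str:
    """TSV: one fold-averaged row per variant plus per-fold rows."""
    lines = ["variant\tscope\trecall\tprecision\taccuracy\tf1\tmcc"]
    for variant, res in results.items():
        lines.append(f"{variant}\tfold-mean\t{res.mean.tsv_row()}")
        for i, m in enumerate(res.per_fold):
            lines.append(f"{variant}\tfold-{i}\t{m.tsv_row()}")
    return "\n".join(lines) + "\n"


def build_manifest(data_dir: str | Path, config: PipelineConfig, stage_times: dict[str, float]) -> RunManifest:
    data_dir = Path(data_dir)
    hashes = {p.name: _file_hash(p) for p in sorted(data_dir.glob("*")) if p.is_file()}
    cfg = {
        "m": config.m,
        "n": config.n,
        "mask": config.mask.tag,
        "filter_w": config.filter_params.w,
        "filter_t": config.filter_params.t,
        "n_folds": config.n_folds,
        "fold_seed": config.fold_seed,
        "sample_seed": config.sample_seed,
        "grid_seed": config.grid_seed,
    }
    return RunManifest(config=cfg, input_hashes=hashes, timings_s=stage_times)


def filter_parameter_sweep(
    dataset: list[ChainBundle],
    config: PipelineConfig = PipelineConfig(),
    w_values: tuple[int, ...] = (6, 10, 14, 18, 22),
) -> dict[int, tuple[int, Metrics]]:
    """For each neighbor count W, the minimum-positive-neighbors threshold T
    with the best fold-averaged MCC (the filter-tuning table of the
    structure path)."""
    by_key = {b.key: b for b in dataset}
    str_cv = cross_validate(dataset, config.train_config("structure"))
    out: dict[int, tuple[int, Metrics]] = {}
    for w in w_values:
        best: tuple[float, int, Metrics] | None = None
        for t in range(1, w + 1):
            tracks = {
                key: filter_false_positives(tr, by_key[key].chain, FilterParams(w=w, t=t))
                for key, tr in str_cv.tracks.items()
            }
            mean = fold_average(_fold_metrics(str_cv.plan.folds, tracks, by_key))
            if best is None or mean.mcc > best[0]:
                best = (mean.mcc, t, mean)
        out[w] = (best[1], best[2])
    return out
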