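"""End-to-end pipeline driver: preprocess, decode, test, aggregate, compare.

Runs every subject through preprocessing, the leave-two-out decoding of all
seven temporal windows, bootstrap SEs and the permutation null; then builds
the group posterior probability map from the best-window decoding maps,
runs the sparseness permutation test, and compares the valence groups.
All randomness flows from ``config.seed`` through named substreams, so a
rerun with the same inputs and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import group_map as gm
from . import valence as vl
from .decode import DecodingResult, decode_subject
from .io import write_map
from .permutation import build_null, rank_test
from .preprocess import WINDOW_TIMES, build_tensor
from .simulate import SubjectDataset

logger = logging.getLogger(__name__)

# substream ids keyed by consumer, so adding one never perturbs the others
_STREAMS = {"bootstrap": 1, "null": 2, "groupperm": 3, "rperm": 4}


@dataclass
class PipelineConfig:
    """Decoder and test parameters; defaults are the study's values."""

    n_top: int = 2000
    min_cluster_select: int = 21
    min_cluster_group: int = 20
    p_thresh: float = 0.33
    n_boot: int = 1000
    n_perm_null: int = 100
    n_perm_group: int = 10000
    n_perm_r: int = 10000
    connectivity: int = 6
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_top", "min_cluster_select", "min_cluster_group",
            "n_boot", "n_perm_null", "n_perm_group", "n_perm_r",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.p_thresh < 1):
            raise ValueError("p_thresh must be in (0, 1)")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    def stream(self, name: str, index: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[name], index])


@dataclass
class SubjectReport:
    """Per-subject decoding outcome with permutation p-values."""

    subject_index: int
    group: str
    result: DecodingResult
    null_values: np.ndarray

    @property
    def significant(self) -> bool:
        return bool(np.min(self.result.p_by_window) < 0.05)


def analyze_subject(
    ds: SubjectDataset, config: PipelineConfig
) -> SubjectReport:
    """Preprocess and decode one subject, including the permutation null."""
    tensor = build_tensor(
        ds.timeseries, ds.mask, ds.trials, ds.tr, ds.run_length_trs
    )
    boot_rng = config.stream("bootstrap", ds.subject_index)
    result = decode_subject(
        tensor,
        n_top=config.n_top,
        min_cluster=config.min_cluster_select,
        connectivity=config.connectivity,
        n_boot=config.n_boot,
        seed=boot_rng,
    )
    null_seed = config.stream("null", ds.subject_index)
    null = build_null(
        tensor,
        n_per_window=config.n_perm_null,
        seed=null_seed,
        n_top=config.n_top,
        min_cluster=config.min_cluster_select,
        connectivity=config.connectivity,
    )
    result.p_by_window = np.array(
        [rank_test(acc, null) for acc in result.accuracy_by_window]
    )
    return SubjectReport(
        subject_index=ds.subject_index,
        group=ds.group,
        result=result,
        null_values=null.values,
    )


def subject_table(reports: list[SubjectReport]) -> pd.DataFrame:
    """Accuracy / SE / p per subject and window (long format)."""
    rows = []
    for rep in reports:
        for w, t in enumerate(rep.result.window_times):
            rows.append(
                {
                    "subject": rep.subject_index + 1,
                    "group": rep.group,
                    "window_s": t,
                    "accuracy": rep.result.accuracy_by_window[w],
                    "se": rep.result.se_by_window[w],
                    "p": rep.result.p_by_window[w],
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(
    cohort: list[SubjectDataset],
    config: PipelineConfig | None = None,
    out_dir=None,
) -> dict:
    """Run the whole analysis over a cohort; optionally write all outputs.

    Returns a JSON-serializable summary; with ``out_dir`` set, also writes
    the per-subject accuracy table, the probability and thresholded group
    maps, the cluster table, the sparseness curves and the Dice matrix.
    """
    config = config or PipelineConfig()
    config.validate()

    reports: list[SubjectReport] = []
    for ds in cohort:
        try:
            reports.append(analyze_subject(ds, config))
        except Exception as err:
            raise RuntimeError(
                f"decoding failed for subject {ds.subject_index}: {err}"
            ) from err
    table = subject_table(reports)

    best_windows = np.array([r.result.best_window for r in reports])
    best_maps = [r.result.best_map.selected for r in reports]
    best_window_idx = np.array([r.result.best_window_index for r in reports])
    maps_by_sw = np.array(
        [[sel.selected for sel in r.result.decoding_maps] for r in reports]
    )

    pmap = gm.build_probability_map(best_maps, contributing_windows=best_window_idx)
    thresholded, clusters = gm.threshold_map(
        pmap,
        p_thresh=config.p_thresh,
        min_cluster=config.min_cluster_group,
        connectivity=config.connectivity,
    )
    sparseness = gm.sparseness_test(
        maps_by_sw,
        best_window_idx,
        n_iter=config.n_perm_group,
        seed=config.stream("groupperm"),
    )

    groups = np.array([r.group for r in reports])
    comparison = None
    if np.unique(groups).size == 2 and min(
        (groups == g).sum() for g in np.unique(groups)
    ) >= 2:
        comparison = vl.compare_groups(
            best_maps,
            groups,
            best_windows,
            n_perm=config.n_perm_r,
            seed=config.stream("rperm"),
        )

    best_accs = np.array(
        [r.result.accuracy_by_window.max() for r in reports]
    )
    idx33 = int(np.argmin(np.abs(sparseness.thresholds - config.p_thresh)))
    summary = {
        "n_subjects": len(reports),
        "n_significant_subjects": int(sum(r.significant for r in reports)),
        "mean_best_accuracy": float(best_accs.mean()),
        "se_best_accuracy": float(
            best_accs.std(ddof=1) / np.sqrt(len(best_accs))
        ),
        "best_window_mean_s": float(best_windows.mean()),
        "best_window_sd_s": float(best_windows.std(ddof=1)),
        "n_suprathreshold_voxels": int(thresholded.sum()),
        "n_clusters": int(len(clusters)),
        "sparseness_p_at_thresh": float(
            sparseness.p_per_threshold[idx33]
        ),
        "config": dataclasses.asdict(config),
    }
    if comparison is not None:
        summary.update(
            {
                "mannwhitney_u": comparison.u_stat,
                "mannwhitney_p": comparison.u_p,
                "dice_ratio_r": comparison.r,
                "r_ci_low": comparison.ci[0],
                "r_ci_high": comparison.ci[1],
                "group_specific_maps": comparison.group_specific,
            }
        )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "subject_accuracy.tsv", sep="\t", index=False)
        clusters.to_csv(out_dir / "cluster_table.tsv", sep="\t", index=False)
        write_map(pmap.prob, out_dir / "probability_map")
        write_map(thresholded.astype(np.uint8), out_dir / "thresholded_map")
        curves = pd.DataFrame(
            {
                "threshold": sparseness.thresholds,
                "observed": sparseness.observed_counts,
                "null_p2_5": np.percentile(sparseness.null_counts, 2.5, axis=0),
                "null_median": np.percentile(sparseness.null_counts, 50, axis=0),
                "null_p97_5": np.percentile(sparseness.null_counts, 97.5, axis=0),
            }
        )
        for w in range(sparseness.fixed_window_counts.shape[0]):
            curves[f"fixed_window_{int(WINDOW_TIMES[w]) if w < len(WINDOW_TIMES) else w}s"] = (
                sparseness.fixed_window_counts[w]
            )
        curves.to_csv(out_dir / "sparseness_curves.tsv", sep="\t", index=False)
        if comparison is not None:
            pd.DataFrame(comparison.dice_matrix).to_csv(
                out_dir / "dice_matrix.tsv", sep="\t", index=False, header=False
            )
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))

    return {
        "summary": summary,
        "subject_table": table,
        "reports": reports,
        "probability_map": pmap,
        "thresholded_map": thresholded,
        "cluster_table": clusters,
        "sparseness": sparseness,
        "comparison": comparison,
    }
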