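"""End-to-end orchestration: simulate -> clean -> ISFC -> permutation test
(per dataset) -> cross-dataset replication.

Every randomized stage records its seed; all outputs are plain text
(tab-separated matrices and tables, JSON sidecars) and a manifest with
SHA-256 hashes makes re-runs verifiable byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as iomod
from .inference import (
    PermutationResult,
    pooled_pair_tensor,
    roi_count_map,
    subject_wise_permutation_test,
)
from .isfc import isfc_difference, median_isfc, unique_pair_count
from .preprocess import CleanedSeries, mean_fd_exclusion, regress_confounds
from .replication import ReplicationResult, replication_analysis, cross_dataset_correlation
from .synthetic import GROUPS, SyntheticConfig, build_dataset, default_two_group_config

logger = logging.getLogger(__name__)

DATASET_ROLES = ("discovery", "replication")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Parameters of a full two-dataset run.

    ``datasets`` maps the roles ``discovery`` and ``replication`` to
    synthetic configurations; per-dataset seeds are derived from the
    global ``seed`` unless set explicitly.
    """

    datasets: dict[str, SyntheticConfig]
    seed: int = 0
    n_permutations: int = 5000
    n_roi_shuffles: int = 5000
    alphas: tuple[float, ...] = (0.05, 0.01)
    fd_threshold: float = 0.5
    output_dir: str = "isfc_out"

    def __post_init__(self) -> None:
        missing = [r for r in DATASET_ROLES if r not in self.datasets]
        if missing:
            raise PipelineError(
                f"run config must define datasets: {', '.join(missing)}"
            )
        self.alphas = tuple(float(a) for a in self.alphas)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        seed = int(raw.get("seed", 0))
        datasets = {}
        for k, role in enumerate(DATASET_ROLES):
            block = dict(raw["datasets"][role])
            block.setdefault("seed", seed * 1000 + k)
            if "weights_by_group" in block or "stimulus_correlation" in block:
                datasets[role] = SyntheticConfig.from_dict(block)
            else:
                datasets[role] = default_two_group_config(**block)
        return cls(
            datasets=datasets,
            seed=seed,
            n_permutations=int(raw.get("n_permutations", 5000)),
            n_roi_shuffles=int(raw.get("n_roi_shuffles", 5000)),
            alphas=tuple(raw.get("alphas", (0.05, 0.01))),
            fd_threshold=float(raw.get("fd_threshold", 0.5)),
            output_dir=str(raw.get("output_dir", "isfc_out")),
        )


def clean_cohort(
    cohort: list[tuple[str, str, np.ndarray, "object"]],
    region_labels: list[str],
    fd_threshold: float = 0.5,
):
    """FD-based exclusion followed by confound regression for a cohort.

    Returns (cleaned subjects, exclusion report).
    """
    kept_ids, report = mean_fd_exclusion(
        [(sid, conf) for sid, _, _, conf in cohort], threshold=fd_threshold
    )
    kept = set(kept_ids)
    cleaned = [
        regress_confounds(
            data, conf, subject_id=sid, group=group, region_labels=region_labels
        )
        for sid, group, data, conf in cohort
        if sid in kept
    ]
    return cleaned, report


def analyze_dataset(
    cleaned: list[CleanedSeries],
    n_permutations: int,
    alphas: tuple[float, ...],
    seed: int,
):
    """Group medians, difference matrix, and the permutation test."""
    pool = pooled_pair_tensor(cleaned)
    summaries = {
        g: median_isfc(pool.restrict(g), group=g) for g in GROUPS
    }
    diff = isfc_difference(summaries[GROUPS[0]], summaries[GROUPS[1]])
    result = subject_wise_permutation_test(
        pool, n_permutations=n_permutations, alphas=alphas, seed=seed
    )
    return summaries, diff, result


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full two-dataset study and write all artifacts.

    Returns the output manifest (also written as ``run_manifest.json``),
    listing every file with its SHA-256 hash plus the seeds, subject
    counts before/after FD exclusion, and pair counts.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "datasets": {}, "files": {}}

    def record(path: Path) -> None:
        manifest["files"][str(path.relative_to(out))] = iomod.file_sha256(path)

    stage = "simulate"
    try:
        per_role: dict[str, PermutationResult] = {}
        diffs: dict[str, np.ndarray] = {}
        for k, role in enumerate(DATASET_ROLES):
            stage = f"simulate[{role}]"
            ds_dir = out / role
            dataset = build_dataset(config.datasets[role])
            manifest_path = iomod.write_dataset(dataset, ds_dir)
            record(manifest_path)
            for entry in json.loads(manifest_path.read_text())["subjects"].values():
                record(ds_dir / entry["timeseries"])
                record(ds_dir / entry["confounds"])

            stage = f"clean[{role}]"
            cohort = iomod.load_cohort(iomod.read_manifest(manifest_path))
            cleaned, report = clean_cohort(
                cohort, dataset.region_labels, fd_threshold=config.fd_threshold
            )
            report_path = ds_dir / "fd_exclusion.tsv"
            report.to_csv(report_path, sep="\t", index=False)
            record(report_path)

            stage = f"isfc[{role}]"
            perm_seed = config.seed * 7919 + k
            summaries, diff, result = analyze_dataset(
                cleaned, config.n_permutations, config.alphas, perm_seed
            )
            r = len(dataset.region_labels)
            logger.info(
                "%s: %d subjects kept, %d regions, %d unique region pairs",
                role, len(cleaned), r, unique_pair_count(r),
            )
            for g, summary in summaries.items():
                p = ds_dir / f"median_isfc_{g}.tsv"
                iomod.write_matrix(p, summary.median_matrix, summary.region_labels)
                record(p)
            diff_path = ds_dir / "isfc_difference.tsv"
            iomod.write_matrix(diff_path, diff, dataset.region_labels)
            record(diff_path)

            stage = f"permtest[{role}]"
            pval_path = ds_dir / "p_values.tsv"
            iomod.write_matrix(pval_path, result.p_values, dataset.region_labels)
            record(pval_path)
            for alpha, mask in result.masks.items():
                mp = ds_dir / f"mask_alpha{alpha:g}.tsv"
                iomod.write_matrix(mp, mask.values, dataset.region_labels)
                record(mp)
                cm = ds_dir / f"roi_counts_alpha{alpha:g}.tsv"
                roi_count_map(mask).to_csv(cm, sep="\t", index=False)
                record(cm)
            sidecar = {
                "seed": perm_seed,
                "n_permutations": result.n_permutations,
                "group_sizes": list(result.group_sizes),
                "alphas": list(config.alphas),
                "n_subjects_before_exclusion": len(cohort),
                "n_subjects_after_exclusion": len(cleaned),
                "n_regions": r,
                "unique_region_pairs": unique_pair_count(r),
            }
            sc_path = ds_dir / "permtest.json"
            sc_path.write_text(json.dumps(sidecar, indent=2) + "\n")
            record(sc_path)
            manifest["datasets"][role] = sidecar
            per_role[role] = result
            diffs[role] = diff

        stage = "replicate"
        alpha0 = config.alphas[0]
        rep_seed = config.seed * 7919 + 97
        disc_mask = per_role["discovery"].masks[alpha0]
        if not disc_mask.significant_pairs():
            raise PipelineError(
                "discovery dataset has no significant pairs at "
                f"alpha={alpha0:g}; replication rate is undefined"
            )
        rep = replication_analysis(
            disc_mask,
            per_role["replication"].masks[alpha0],
            n_shuffles=config.n_roi_shuffles,
            seed=rep_seed,
        )
        r_cross, p_cross = cross_dataset_correlation(
            diffs["discovery"],
            diffs["replication"],
            n_shuffles=config.n_roi_shuffles,
            seed=rep_seed + 1,
        )
        labels = per_role["discovery"].region_labels
        ov_path = out / "overlap.tsv"
        iomod.write_matrix(ov_path, rep.overlap, labels)
        record(ov_path)
        pairs_path = out / "replicated_pairs.tsv"
        mean_diff = (diffs["discovery"] + diffs["replication"]) / 2.0
        with open(pairs_path, "w") as fh:
            fh.write("region_i\tregion_j\tsign\tmean_difference\n")
            for i, j, s in rep.replicated_pairs:
                fh.write(
                    f"{labels[i]}\t{labels[j]}\t{s}\t{mean_diff[i, j]:.10g}\n"
                )
        record(pairs_path)
        summary = {
            "replication_rate": rep.rate,
            "replication_p": rep.p_value,
            "n_replicated_pairs": len(rep.replicated_pairs),
            "cross_dataset_r": r_cross,
            "cross_dataset_p": p_cross,
            "n_shuffles": config.n_roi_shuffles,
            "alpha": alpha0,
            "seed": rep_seed,
        }
        sum_path = out / "replication.json"
        sum_path.write_text(json.dumps(summary, indent=2) + "\n")
        record(sum_path)
        manifest["replication"] = summary
    except Exception as exc:
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    manifest_path = out / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
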