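"""End-to-end study orchestration: simulate -> assign -> align -> analyze ->
report.

Each stage reads the previous stage's files from the run directory and
writes its own, so stages are runnable standalone (see
:mod:`vespawing.cli`). ``run_pipeline`` chains them and returns the
collected statistical report plus a manifest (config snapshot, seed,
package versions, per-file SHA-256 digests) that makes a run reproducible
and auditable.

Analysis choices mirrored from the study design: the whole-sample analyses
(size ANOVA, MANCOVA, CVA sweep) use every measured wing and all retained
PCs; the focused tests (Welch t, Hotelling T-squared raw and
allometry-corrected, angle comparisons) use balanced subsamples (default
34) of the two largest patrilines of each colony, drawn by seeded
permutation of the canonical specimen order.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import SimulationConfig, default_config, load_config, save_config, _to_dict
from . import io_formats, pedigree, shapestats, superimpose, wing_synth

__all__ = [
    "StatReport",
    "RunManifest",
    "run_pipeline",
    "simulate_stage",
    "assign_stage",
    "align_stage",
    "analyze_stage",
    "report_stage",
]


@dataclass
class StatReport:
    """All result tables of one run, keyed by analysis name."""

    tables: dict = field(default_factory=dict)


@dataclass
class RunManifest:
    config: dict
    seed: int
    versions: dict
    digests: dict
    warnings: list


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage}: expected upstream artifact {path} is missing"
        )
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# --------------------------------------------------------------------------
# simulate
# --------------------------------------------------------------------------

def simulate_stage(config: SimulationConfig, outdir, seed: int) -> wing_synth.StudyData:
    """Simulate the study and write genotypes, wings and truth files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    study = wing_synth.simulate_study(config, seed)

    with open(out / "genotypes.csv", "w") as fh:
        fh.write(io_formats.write_genotypes(study.workers, study.queens))

    wing_configs = [r.config for r in study.wings.records]
    (out / "wings.tps").write_text(
        io_formats.write_tps(io_formats.configurations_to_tps(wing_configs))
    )
    pd.DataFrame(
        {
            "specimen_id": [r.specimen_id for r in study.wings.records],
            "colony_id": [r.colony_id for r in study.wings.records],
            "damaged": [int(r.damaged) for r in study.wings.records],
        }
    ).to_csv(out / "wings_meta.csv", index=False)
    (out / "error_study.tps").write_text(
        io_formats.write_tps(io_formats.configurations_to_tps(study.error_records))
    )

    truth = {
        "colonies": [
            {
                "colony_id": t.colony_id,
                "father_haplotypes": t.father_haplotypes,
                "worker_patriline_labels": t.worker_patriline_labels,
                "allele_frequencies": {
                    k: v.tolist() for k, v in t.allele_frequencies.items()
                },
                "size_effects": {
                    "colony": t.true_size_effects["colony"],
                    "patriline": t.true_size_effects["patriline"].tolist(),
                },
            }
            for t in study.truths
        ],
        "error_study_labels": study.error_labels,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    save_config(config, out / "config_snapshot.yaml")
    return study


# --------------------------------------------------------------------------
# assign
# --------------------------------------------------------------------------

def assign_stage(outdir) -> dict:
    """Filter genotypes and infer patrilines per colony.

    Writes ``assignment.csv`` (specimen, colony, patriline or exclusion
    reason) and ``paternity.json`` (inferred haplotypes, patriline
    percentages, paternal allele frequencies, non-detection probability).
    """
    out = Path(outdir)
    workers, queens = io_formats.read_genotypes(
        _require(out / "genotypes.csv", "assign")
    )

    rows = []
    colony_results = {}
    assignments = []
    for colony_id in sorted(queens):
        queen = queens[colony_id]
        colony_workers = [w for w in workers if w.colony_id == colony_id]
        retained, excluded = pedigree.filter_amplification(colony_workers)
        maternal = [w for w in retained if pedigree.check_maternity(w, queen)]
        mismatched = [w for w in retained if not pedigree.check_maternity(w, queen)]
        assignment = pedigree.infer_patrilines(maternal, queen)
        for w in excluded:
            assignment.excluded[w.specimen_id] = "amplification-failure"
        for w in mismatched:
            assignment.excluded[w.specimen_id] = "maternity-mismatch"
        assignments.append(assignment)

        n_genotyped = len(maternal)
        freqs_pct = pedigree.patriline_frequencies(assignment, n_genotyped)
        colony_results[colony_id] = {
            "n_workers": len(colony_workers),
            "n_genotyped": n_genotyped,
            "n_excluded": len(excluded) + len(mismatched),
            "n_patrilines": assignment.n_patrilines,
            "patriline_counts": {
                str(k): v for k, v in sorted(assignment.counts().items())
            },
            "patriline_percent": {str(k): v for k, v in freqs_pct.items()},
            "paternal_haplotypes": [
                {
                    locus: sorted(a) if a is not None else None
                    for locus, a in h.items()
                }
                for h in assignment.haplotypes
            ],
        }
        for w in colony_workers:
            label = assignment.labels.get(w.specimen_id)
            rows.append(
                {
                    "specimen_id": w.specimen_id,
                    "colony_id": colony_id,
                    "patriline": label if label is not None else "",
                    "excluded_reason": assignment.excluded.get(w.specimen_id, ""),
                }
            )

    freq_table = pedigree.paternal_allele_frequencies(assignments)
    paternity = {
        "colonies": colony_results,
        "paternal_allele_frequencies": {
            locus: {str(a): q for a, q in sorted(table.items())}
            for locus, table in freq_table.freqs.items()
        },
        "non_detection_probability": pedigree.non_detection_probability(freq_table),
    }
    pd.DataFrame(rows).to_csv(out / "assignment.csv", index=False)
    (out / "paternity.json").write_text(json.dumps(paternity, indent=1))
    return paternity


# --------------------------------------------------------------------------
# align
# --------------------------------------------------------------------------

def _write_matrix(path, ids: pd.DataFrame, matrix: np.ndarray, prefix: str):
    df = pd.concat(
        [
            ids.reset_index(drop=True),
            pd.DataFrame(
                matrix, columns=[f"{prefix}{j}" for j in range(matrix.shape[1])]
            ),
        ],
        axis=1,
    )
    df.to_csv(path, index=False)


def align_stage(outdir, scale_coordinates: bool = True) -> dict:
    """Superimpose the measured wings (and the error study) and run the PCA.

    Damaged wings are dropped before the GPA. Writes aligned/tangent
    coordinates, log centroid sizes, PCA scores and eigenvalues, the
    consensus, and the error-study tangent coordinates.
    """
    out = Path(outdir)
    records = io_formats.read_tps(str(_require(out / "wings.tps", "align")))
    configs = io_formats.tps_to_configurations(records, scale_coordinates)
    meta = pd.read_csv(_require(out / "wings_meta.csv", "align"))
    damaged = set(meta.loc[meta["damaged"] == 1, "specimen_id"])
    measured = [c for c in configs if c.specimen_id not in damaged]

    sample = superimpose.gpa(measured)
    ids = pd.DataFrame(
        {
            "specimen_id": [c.specimen_id for c in measured],
            "colony_id": [c.colony_id for c in measured],
        }
    )
    flat = sample.aligned.reshape(sample.n_configurations, -1)
    _write_matrix(out / "aligned.csv", ids, flat, "c")
    _write_matrix(out / "tangent.csv", ids, sample.tangent, "t")
    pd.DataFrame(
        {
            "specimen_id": ids["specimen_id"],
            "colony_id": ids["colony_id"],
            "centroid_size": sample.centroid_sizes,
            "log_centroid_size": sample.log_centroid_sizes,
        }
    ).to_csv(out / "sizes.csv", index=False)
    np.savetxt(out / "consensus.csv", sample.consensus, delimiter=",")

    pca = superimpose.shape_pca(sample.tangent)
    _write_matrix(out / "pca_scores.csv", ids, pca.scores, "PC")
    pd.DataFrame(
        {
            "component": np.arange(1, pca.n_components + 1),
            "eigenvalue": pca.eigenvalues,
            "variance_fraction": pca.variance_fraction,
        }
    ).to_csv(out / "pca_eigenvalues.csv", index=False)

    summary = {
        "n_measured": len(measured),
        "n_damaged": len(configs) - len(measured),
        "n_components": pca.n_components,
        "gpa_iterations": sample.iterations_used,
    }

    error_path = out / "error_study.tps"
    if error_path.exists():
        err_records = io_formats.read_tps(str(error_path))
        err_configs = io_formats.tps_to_configurations(err_records, scale_coordinates)
        err_sample = superimpose.gpa(err_configs)
        err_ids = pd.DataFrame(
            {
                "specimen_id": [c.specimen_id for c in err_configs],
                "colony_id": [c.colony_id for c in err_configs],
                "mounting": [c.mounting for c in err_configs],
                "digitization": [c.digitization for c in err_configs],
            }
        )
        _write_matrix(out / "error_tangent.csv", err_ids, err_sample.tangent, "t")
        summary["n_error_records"] = len(err_configs)

    (out / "align_summary.json").write_text(json.dumps(summary, indent=1))
    return summary


# --------------------------------------------------------------------------
# analyze
# --------------------------------------------------------------------------

def _load_matrix(path, prefix: str) -> tuple[pd.DataFrame, np.ndarray]:
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c.startswith(prefix) and c[len(prefix):].isdigit()]
    cols = sorted(cols, key=lambda c: int(c[len(prefix):]))
    return df.drop(columns=cols), df[cols].to_numpy(float)


def _balanced_subsample(ids, mask_a, mask_b, size, rng):
    """Seeded-permutation balanced draw from two patrilines."""
    idx_a = np.flatnonzero(mask_a)
    idx_b = np.flatnonzero(mask_b)
    n = min(size, len(idx_a), len(idx_b))
    order_a = idx_a[np.argsort(ids[idx_a])][rng.permutation(len(idx_a))][:n]
    order_b = idx_b[np.argsort(ids[idx_b])][rng.permutation(len(idx_b))][:n]
    return np.sort(order_a), np.sort(order_b)


def analyze_stage(
    outdir,
    seed: int,
    n_pcs=None,
    subsample_size: int = 34,
    angle_draws: int = 10000,
) -> StatReport:
    """Run the statistical battery on the aligned, assigned dataset.

    ``n_pcs``: either a single PC count or an iterable for the CVA sweep;
    default sweeps 2..(retained PCs).
    """
    out = Path(outdir)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2654435769]))
    report = StatReport()

    assignment = pd.read_csv(
        _require(out / "assignment.csv", "analyze"),
        dtype={"specimen_id": str, "colony_id": str},
        keep_default_na=False,
    )
    labels_by_specimen = {
        row.specimen_id: int(row.patriline)
        for row in assignment.itertuples()
        if str(row.patriline) not in ("", "nan")
    }

    sizes = pd.read_csv(_require(out / "sizes.csv", "analyze"))
    tan_ids, tangent = _load_matrix(_require(out / "tangent.csv", "analyze"), "t")
    _, aligned_flat = _load_matrix(_require(out / "aligned.csv", "analyze"), "c")
    score_ids, scores = _load_matrix(_require(out / "pca_scores.csv", "analyze"), "PC")
    consensus = np.loadtxt(out / "consensus.csv", delimiter=",")

    # keep only wings with an assigned patriline (genotyping attrition)
    keep = np.array(
        [s in labels_by_specimen for s in tan_ids["specimen_id"]], dtype=bool
    )
    specimen_ids = tan_ids["specimen_id"].to_numpy()[keep]
    colony = tan_ids["colony_id"].to_numpy()[keep]
    patriline = np.array([labels_by_specimen[s] for s in specimen_ids])
    tangent = tangent[keep]
    aligned = aligned_flat[keep].reshape(keep.sum(), -1, 2)
    scores = scores[keep]
    logcs = sizes["log_centroid_size"].to_numpy()[keep]

    sample = superimpose.AlignedSample(
        consensus=consensus,
        aligned=aligned,
        centroid_sizes=np.exp(logcs),
        log_centroid_sizes=logcs,
        tangent=tangent,
        iterations_used=0,
        specimen_ids=list(specimen_ids),
    )

    # --- size: nested ANOVA, variance components, Welch tests ------------
    report.tables["size_anova"] = shapestats.size_nested_anova(
        logcs, colony, patriline
    )
    vc = shapestats.size_variance_components(logcs, colony, patriline)
    report.tables["variance_components"] = asdict(vc)

    # --- whole-sample shape analyses --------------------------------------
    report.tables["mancova"] = shapestats.shape_mancova(
        scores, logcs, colony, patriline
    )
    cell = np.array([f"{c}|{p}" for c, p in zip(colony, patriline)])
    if n_pcs is None:
        sweep_range = range(2, scores.shape[1] + 1)
    elif np.isscalar(n_pcs):
        sweep_range = [int(n_pcs)]
    else:
        sweep_range = [int(k) for k in n_pcs]
    report.tables["cva_sweep"] = shapestats.cva_sweep(scores, cell, sweep_range)

    report.tables["distances"] = asdict(
        shapestats.group_mean_distances(sample, patriline, colony)
    )

    # --- measurement error -------------------------------------------------
    err_path = out / "error_tangent.csv"
    if err_path.exists():
        err_ids, err_tangent = _load_matrix(err_path, "t")
        err_group = np.array(
            [labels_by_specimen.get(s, -1) for s in err_ids["specimen_id"]]
        )
        known = err_group >= 0
        report.tables["procrustes_anova"] = shapestats.procrustes_anova(
            err_tangent[known],
            err_ids["specimen_id"].to_numpy()[known],
            err_ids["mounting"].to_numpy()[known],
            err_ids["digitization"].to_numpy()[known],
            err_group[known],
        )

    # --- main-patriline pair analyses per colony ---------------------------
    welch = {}
    hotelling = {}
    allometry = {}
    pair_diffs = {}
    for c in sorted(set(colony)):
        mask_c = colony == c
        counts = pd.Series(patriline[mask_c]).value_counts()
        if len(counts) < 2:
            continue
        top = sorted(counts.index[counts == counts.iloc[0]])[:2]
        if len(top) < 2:
            second = counts.drop(index=top[0])
            top = [top[0], sorted(second.index[second == second.iloc[0]])[0]]
        a, b = sorted(top)
        idx_a, idx_b = _balanced_subsample(
            specimen_ids,
            mask_c & (patriline == a),
            mask_c & (patriline == b),
            subsample_size,
            rng,
        )
        t_stat, df_w, p_w = shapestats.welch_t(logcs[idx_a], logcs[idx_b])
        welch[c] = {
            "patrilines": [int(a), int(b)],
            "n": [int(idx_a.size), int(idx_b.size)],
            "t": t_stat,
            "df": df_w,
            "p": p_w,
        }

        sub = np.concatenate([idx_a, idx_b])
        # PCs usable by Hotelling: shape dimension, but small subsamples cap
        # it (pooled covariance rank is n1 + n2 - 2; leave slack so the
        # smallest retained eigenvalue stays numerically positive)
        max_p = sub.size - 4
        sub_pca = superimpose.shape_pca(tangent[sub])
        m = min(sub_pca.n_components, tangent.shape[1] - 4, max_p)
        sub_scores = sub_pca.scores[:, :m]
        half = idx_a.size
        res = shapestats.hotelling_t2(sub_scores[:half], sub_scores[half:])
        hotelling[c] = {"raw": asdict(res)}

        cac = shapestats.common_allometric_component(
            tangent[sub], logcs[sub], patriline[sub]
        )
        allometry[c] = {
            "cac_norm": float(np.linalg.norm(cac.cac)),
            "cac_norm_se": float(np.linalg.norm(cac.se)),
        }
        corr_pca = superimpose.shape_pca(cac.corrected)
        mc = min(corr_pca.n_components, tangent.shape[1] - 4, max_p)
        corr_scores = corr_pca.scores[:, :mc]
        res_c = shapestats.hotelling_t2(corr_scores[:half], corr_scores[half:])
        hotelling[c]["allometry_corrected"] = asdict(res_c)

        pair_diffs[c] = tangent[idx_a].mean(axis=0) - tangent[idx_b].mean(axis=0)

    report.tables["welch"] = welch
    report.tables["hotelling"] = hotelling
    report.tables["allometry"] = allometry

    # --- angles between group-difference vectors ---------------------------
    colonies = sorted(set(colony))
    angles = {}
    if len(colonies) >= 2 and len(pair_diffs) >= 2:
        d_colony = tangent[colony == colonies[0]].mean(axis=0) - tangent[
            colony == colonies[1]
        ].mean(axis=0)
        vectors = {"colony": d_colony}
        for c in colonies[:2]:
            vectors[f"patrilines_{c}"] = pair_diffs[c]
        names = list(vectors)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                res = shapestats.angle_null_test(
                    vectors[names[i]],
                    vectors[names[j]],
                    tangent,
                    n_draws=angle_draws,
                    seed=rng,
                )
                angles[f"{names[i]}__vs__{names[j]}"] = asdict(res)
    report.tables["angles"] = angles

    _write_report_tables(out, report)
    return report


def _write_report_tables(out: Path, report: StatReport) -> None:
    for name, table in report.tables.items():
        if isinstance(table, pd.DataFrame):
            table.to_csv(out / f"{name}.csv")
        else:
            (out / f"{name}.json").write_text(
                json.dumps(table, indent=1, default=_jsonable)
            )


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# --------------------------------------------------------------------------
# report
# --------------------------------------------------------------------------

_STAGE_FILES = [
    "config_snapshot.yaml",
    "genotypes.csv",
    "wings.tps",
    "wings_meta.csv",
    "error_study.tps",
    "truth.json",
    "assignment.csv",
    "paternity.json",
    "aligned.csv",
    "tangent.csv",
    "sizes.csv",
    "consensus.csv",
    "pca_scores.csv",
    "pca_eigenvalues.csv",
    "error_tangent.csv",
    "align_summary.json",
    "size_anova.csv",
    "variance_components.json",
    "mancova.csv",
    "cva_sweep.json",
    "distances.json",
    "procrustes_anova.csv",
    "welch.json",
    "hotelling.json",
    "allometry.json",
    "angles.json",
]


def report_stage(outdir, seed: int, config: SimulationConfig | None = None,
                 run_warnings: list | None = None) -> RunManifest:
    """Bundle stored stage outputs into ``report.json`` plus a manifest with
    per-file SHA-256 digests; no statistics are recomputed."""
    out = Path(outdir)
    collected = {}
    digests = {}
    for name in _STAGE_FILES:
        path = out / name
        if not path.exists():
            continue
        digests[name] = _sha256(path)
        if name.endswith(".json"):
            collected[name[:-5]] = json.loads(path.read_text())
    (out / "report.json").write_text(json.dumps(collected, indent=1))

    if config is None:
        config = load_config(_require(out / "config_snapshot.yaml", "report"))
    manifest = RunManifest(
        config=_to_dict(config),
        seed=seed,
        versions={
            "vespawing": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        digests=digests,
        warnings=run_warnings or [],
    )
    (out / "manifest.json").write_text(json.dumps(asdict(manifest), indent=1))
    return manifest


# --------------------------------------------------------------------------
# in-memory summary used for generator calibration and recovery checks
# --------------------------------------------------------------------------

def calibration_statistics(config: SimulationConfig, seed: int) -> dict:
    """Simulate one study in memory and return the calibration summaries:
    the between-/within-patriline Procrustes-distance statistics and the
    intra-patriline log-size variance component, computed with *inferred*
    patriline labels exactly as the file-based pipeline would."""
    study = wing_synth.simulate_study(config, seed)
    labels: dict[str, int] = {}
    for truth in study.truths:
        colony_workers = [
            w for w in study.workers if w.colony_id == truth.colony_id
        ]
        retained, _ = pedigree.filter_amplification(colony_workers)
        maternal = [
            w for w in retained
            if pedigree.check_maternity(w, truth.queen_genotype)
        ]
        assignment = pedigree.infer_patrilines(maternal, truth.queen_genotype)
        labels.update(assignment.labels)

    records = [r for r in study.wings.measured() if r.specimen_id in labels]
    sample = superimpose.gpa([r.config for r in records])
    colony = np.array([r.colony_id for r in records])
    patriline = np.array([labels[r.specimen_id] for r in records])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        distances = shapestats.group_mean_distances(sample, patriline, colony)
    vc = shapestats.size_variance_components(
        sample.log_centroid_sizes, colony, patriline
    )
    return {
        "between_mean": distances.between_mean,
        "within_mean": distances.within_mean,
        "s2_intra_patriline": vc.s2_intra_patriline,
        "n_wings": len(records),
    }


# --------------------------------------------------------------------------
# full run
# --------------------------------------------------------------------------

def run_pipeline(
    config: SimulationConfig | str | Path | None,
    outdir,
    seed: int,
    n_pcs=None,
    subsample_size: int = 34,
    angle_draws: int = 10000,
) -> tuple[StatReport, RunManifest]:
    """Execute the full study on a fresh simulation.

    ``config`` may be a :class:`SimulationConfig`, a path to a YAML config,
    or ``None`` for the shipped defaults. Any stage failure is re-raised
    with the stage name prepended.
    """
    if config is None:
        config = default_config(seed)
    elif isinstance(config, (str, Path)):
        config = load_config(config)
    caught: list[str] = []
    stage = "simulate"
    try:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            simulate_stage(config, outdir, seed)
            stage = "assign"
            assign_stage(outdir)
            stage = "align"
            align_stage(outdir)
            stage = "analyze"
            report = analyze_stage(
                outdir,
                seed,
                n_pcs=n_pcs,
                subsample_size=subsample_size,
                angle_draws=angle_draws,
            )
        caught = [str(w.message) for w in wlist]
        stage = "report"
        manifest = report_stage(outdir, seed, config, caught)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return report, manifest
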