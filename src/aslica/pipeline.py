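"""End-to-end orchestration: subtraction -> ICA -> classify -> regress ->
fit -> metrics, plus the multi-method comparison experiment.

A dataset directory follows the layout written by
:func:`aslica.synthgen.write_dataset` (``raw.nii.gz``, ``m0.nii.gz``,
PVE maps, masks, ``raw.par``, ``acq.yaml``).  Every run writes its
intermediates and a machine-readable provenance record; identical
config + inputs give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from aslica import __version__
from aslica.asl_io import (
    ComponentLabels,
    read_acquisition,
    read_motion_par,
    read_series,
    write_labels,
    write_report,
    write_series,
    ImageSeries,
)
from aslica.classify import (
    ComponentClassifier,
    RuleCutoffs,
    extract_features,
    predict_labels,
    rule_classify,
    train_classifier,
)
from aslica.decompose import SpatialICA
from aslica.denoise import acompcor, enable_select, nonaggressive_regress
from aslica.evaluate import (
    delta_std_map,
    poor_fit_count,
    repeatability_cov,
    repetition_curve,
    snr_summary,
)
from aslica.kinetics import KineticConstants, fit_dataset
from aslica.preprocess import AslSub, subtract_pairs, tissue_masks

logger = logging.getLogger("aslica")

__all__ = ["PipelineConfig", "load_dataset", "run_denoise_pipeline", "run_comparison"]


@dataclass
class PipelineConfig:
    """Validated settings for a pipeline run.

    ``master_seed`` fans out deterministically to ICA restarts and
    classifier fitting so stochastic stages are reproducible.
    """

    pve_threshold: float = 0.70
    ica_dim: int | None = None
    classifier_mode: str = "rule"  # rule | trained
    model_path: str | None = None
    denoise_method: str = "ica-nonaggr"  # ica-nonaggr | ica-aggr | acompcor | enable
    acompcor_n_components: int = 5
    rule_cutoffs: RuleCutoffs = field(default_factory=RuleCutoffs)
    kinetic: KineticConstants = field(default_factory=KineticConstants)
    master_seed: int = 0
    n_ica_restarts: int = 5
    tpr_floor: float = 0.90
    fit_mask: str = "gm"  # gm | brain
    compute_repeatability: bool = True
    repetition_curves: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.pve_threshold <= 1):
            raise ValueError("pve_threshold must lie in (0, 1]")
        if self.classifier_mode not in ("rule", "trained"):
            raise ValueError(f"unknown classifier mode {self.classifier_mode!r}")
        if self.denoise_method not in (
            "ica-nonaggr",
            "ica-aggr",
            "acompcor",
            "enable",
            "none",
        ):
            raise ValueError(f"unknown denoise method {self.denoise_method!r}")
        if self.fit_mask not in ("gm", "brain"):
            raise ValueError("fit_mask must be 'gm' or 'brain'")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if "rule_cutoffs" in payload and isinstance(payload["rule_cutoffs"], dict):
            payload["rule_cutoffs"] = RuleCutoffs(**payload["rule_cutoffs"])
        if "kinetic" in payload and isinstance(payload["kinetic"], dict):
            payload["kinetic"] = KineticConstants(**payload["kinetic"])
        return cls(**payload)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class LoadedDataset:
    """A dataset directory pulled into memory and subtracted."""

    sub: AslSub
    m0: ImageSeries
    edge_ribbon: np.ndarray
    periventricular: np.ndarray
    wm_csf: np.ndarray
    dataset_id: str


def load_dataset(directory: str | Path, config: PipelineConfig) -> LoadedDataset:
    """Read a dataset directory and produce the subtracted series + masks."""
    directory = Path(directory)
    acq = read_acquisition(directory / "acq.yaml")
    raw = read_series(directory / "raw.nii.gz")
    m0 = read_series(directory / "m0.nii.gz")
    motion = read_motion_par(directory / "raw.par", n_volumes=raw.nt)
    pve_gm = read_series(directory / "pve_gm.nii.gz")
    brain = read_series(directory / "brain_mask.nii.gz")
    for img, name in [(m0, "m0"), (pve_gm, "pve_gm"), (brain, "brain_mask")]:
        if not raw.same_grid(img):
            raise ValueError(f"{name} grid/affine does not match raw series")

    gm, nonbrain = tissue_masks(pve_gm, brain, config.pve_threshold)
    sub = subtract_pairs(raw, acq, motion=motion)
    sub.gm_mask = gm
    sub.brain_mask = brain.data[..., 0] > 0.5
    sub.nonbrain_mask = nonbrain

    def optional_mask(name):
        p = directory / f"{name}.nii.gz"
        return (read_series(p).data[..., 0] > 0.5) if p.exists() else np.zeros(sub.grid, bool)

    # aCompCor noise ROI: voxels dominated by WM + CSF, clear of the GM mask
    wm_csf = np.zeros(sub.grid, bool)
    wm_p, csf_p = directory / "pve_wm.nii.gz", directory / "pve_csf.nii.gz"
    if wm_p.exists() and csf_p.exists():
        pw = read_series(wm_p).data[..., 0]
        pc = read_series(csf_p).data[..., 0]
        wm_csf = ((pw + pc) >= 0.9) & ~gm

    return LoadedDataset(
        sub=sub,
        m0=m0,
        edge_ribbon=optional_mask("edge_ribbon"),
        periventricular=optional_mask("periventricular"),
        wm_csf=wm_csf,
        dataset_id=directory.name,
    )


def _decompose_and_classify(
    ds: LoadedDataset,
    config: PipelineConfig,
    model: ComponentClassifier | None = None,
):
    """Shared ICA + feature extraction + labeling step."""
    ica = SpatialICA(
        n_components=config.ica_dim,
        n_restarts=config.n_ica_restarts,
        random_state=config.master_seed,
    ).fit(ds.sub)
    features = extract_features(
        ica.decomposition_,
        ds.sub,
        ds.sub.acq,
        gm_mask=ds.sub.gm_mask,
        edge_mask=ds.edge_ribbon,
        csf_mask=ds.periventricular,
    )
    if model is not None:
        labels = predict_labels(model, features)
    else:
        labels = rule_classify(features, config.rule_cutoffs)
    return ica, features, labels


def _denoise(ds: LoadedDataset, config: PipelineConfig, ica, labels):
    method = config.denoise_method
    if method == "none":
        from aslica.denoise import DenoiseResult

        return DenoiseResult(sub=ds.sub, method="raw")
    if method in ("ica-nonaggr", "ica-aggr"):
        return nonaggressive_regress(
            ds.sub,
            ica.decomposition_.mixing,
            labels.noise_indices,
            aggressive=(method == "ica-aggr"),
        )
    if method == "acompcor":
        roi = ds.wm_csf if np.any(ds.wm_csf) else (ds.periventricular & ~ds.sub.gm_mask)
        if not np.any(roi):
            raise ValueError("empty aCompCor noise ROI")
        return acompcor(ds.sub, roi, config.acompcor_n_components)
    return enable_select(ds.sub)


def _metrics(
    ds: LoadedDataset, cleaned: AslSub, config: PipelineConfig, method: str
) -> dict:
    gm = ds.sub.gm_mask
    mask = gm if config.fit_mask == "gm" else ds.sub.brain_mask
    fit = fit_dataset(cleaned, ds.m0, config.kinetic, mask=mask)
    record = {"dataset": ds.dataset_id, "method": method}
    record.update(snr_summary(fit, gm))
    record["poor_fit_count"] = poor_fit_count(fit, gm)
    if config.compute_repeatability and cleaned.acq.n_repeats >= 2:
        try:
            record["repeatability_cov"] = repeatability_cov(
                cleaned, ds.m0, config.kinetic, gm, strict=(method != "enable")
            )
        except ValueError:
            record["repeatability_cov"] = np.nan
    return record


def run_denoise_pipeline(
    dataset_dir: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Run the full single-dataset pipeline; write intermediates + provenance.

    Returns the metric record (also written to ``metrics.csv``).
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = load_dataset(dataset_dir, config)
    logger.info("loaded %s: %d volumes", ds.dataset_id, ds.sub.n_volumes)

    model = None
    if config.classifier_mode == "trained":
        if not config.model_path:
            raise ValueError("trained mode requires model_path")
        model = ComponentClassifier.from_json(config.model_path)

    ica, features, labels = _decompose_and_classify(ds, config, model)
    logger.info(
        "ICA: %d components, %d labeled noise",
        ica.n_components_,
        len(labels.noise_indices),
    )
    ica.save(out / "ica", affine=ds.sub.affine, voxel_sizes=ds.sub.voxel_sizes)
    features.to_csv(out / "features.csv")
    write_labels(labels, out / "labels.txt")

    result = _denoise(ds, config, ica, labels)
    write_series(
        ImageSeries(result.sub.data, ds.sub.affine, ds.sub.voxel_sizes),
        out / "denoised.nii.gz",
    )
    if result.method == "enable":
        (out / "retained_volumes.txt").write_text(
            " ".join(str(int(i)) for i in result.sub.volume_ids) + "\n"
        )

    dstd = delta_std_map(ds.sub, result.sub)
    write_series(
        ImageSeries(dstd, ds.sub.affine, ds.sub.voxel_sizes),
        out / "delta_std.nii.gz",
    )

    record = _metrics(ds, result.sub, config, result.method)
    write_report([record], out / "metrics.csv")

    mask = ds.sub.gm_mask if config.fit_mask == "gm" else ds.sub.brain_mask
    fit = fit_dataset(result.sub, ds.m0, config.kinetic, mask=mask)
    fit.save(out / "fit")

    provenance = {
        "aslica_version": __version__,
        "numpy_version": np.__version__,
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "dataset": str(Path(dataset_dir).resolve()),
        "master_seed": config.master_seed,
        "n_components": int(ica.n_components_),
        "noise_components_1based": [i + 1 for i in labels.noise_indices],
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
    return record


METHODS = ("raw", "ica-rule", "ica-trained", "acompcor", "enable")


def run_comparison(
    corpus_dirs: list[str | Path],
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    methods: tuple[str, ...] = METHODS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare denoising strategies across a corpus.

    Per dataset, each requested method is applied and the metric record
    collected.  The ``ica-trained`` arm trains the classifier with
    leave-one-subject-out over the corpus, using the rule labels as the
    training truth (the operationalized manual rating).  With
    ``config.repetition_curves`` the repetition-reduction table is
    produced for raw and rule-denoised data.

    Returns ``(metric table, repetition-curve table)``.
    """
    config = config or PipelineConfig()
    if "ica-trained" in methods and len(corpus_dirs) < 2:
        raise ValueError("LOSO training requires >= 2 subjects")

    datasets = [load_dataset(d, config) for d in corpus_dirs]
    per_subject = {}
    for ds in datasets:
        ica, features, rule_labels = _decompose_and_classify(ds, config, model=None)
        per_subject[ds.dataset_id] = (ds, ica, features, rule_labels)

    records: list[dict] = []
    curves: list[dict] = []
    for sid, (ds, ica, features, rule_labels) in per_subject.items():
        for method in methods:
            if method == "raw":
                cleaned = ds.sub
            elif method == "ica-rule":
                cleaned = nonaggressive_regress(
                    ds.sub, ica.decomposition_.mixing, rule_labels.noise_indices
                ).sub
            elif method == "ica-trained":
                training = [
                    (feat, lab, other)
                    for other, (_, _, feat, lab) in per_subject.items()
                    if other != sid
                ]
                model = train_classifier(
                    training,
                    tpr_floor=config.tpr_floor,
                    random_state=config.master_seed,
                )
                pred = predict_labels(model, features)
                cleaned = nonaggressive_regress(
                    ds.sub, ica.decomposition_.mixing, pred.noise_indices
                ).sub
            elif method == "acompcor":
                roi = ds.wm_csf if np.any(ds.wm_csf) else (ds.periventricular & ~ds.sub.gm_mask)
                cleaned = acompcor(ds.sub, roi, config.acompcor_n_components).sub
            elif method == "enable":
                cleaned = enable_select(ds.sub).sub
            else:
                raise ValueError(f"unknown method {method!r}")
            records.append(_metrics(ds, cleaned, config, method))

        if config.repetition_curves:
            gm = ds.sub.gm_mask

            def rule_denoiser(s: AslSub) -> AslSub:
                ica_k = SpatialICA(
                    n_restarts=config.n_ica_restarts,
                    random_state=config.master_seed,
                ).fit(s)
                feat = extract_features(
                    ica_k.decomposition_,
                    s,
                    s.acq,
                    gm_mask=gm,
                    edge_mask=ds.edge_ribbon,
                    csf_mask=ds.periventricular,
                )
                lab = rule_classify(feat, config.rule_cutoffs)
                return nonaggressive_regress(
                    s, ica_k.decomposition_.mixing, lab.noise_indices
                ).sub

            for tag, den in [("raw", None), ("ica-rule", rule_denoiser)]:
                for row in repetition_curve(
                    ds.sub, ds.m0, config.kinetic, gm, denoiser=den
                ):
                    curves.append({"dataset": sid, "method": tag, **row})

    metrics_df = pd.DataFrame(records)
    curves_df = pd.DataFrame(curves)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(metrics_df, out / "comparison.csv")
        if not curves_df.empty:
            curves_df.to_csv(out / "repetition_curves.csv", index=False)
    return metrics_df, curves_df
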