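"""End-to-end experiment runner: dataset -> features -> training -> metrics.

One *experiment* is a tissue-mask combination (e.g. WSI only, or
WSI + EPN + DMN-M) evaluated at one or more scales over several training
seeds.  The data split is fixed: the manifest's train half is further cut
into fit/validation cases once (stratified, fixed internal seed), and
only the training seed varies between runs, so per-seed variation
reflects optimization stochasticity alone.  The frozen patch encoder
plays the role of a pretrained backbone: its weights depend on its own
seed, never on the training seed, so all seeds see identical features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .evalrep import (ConfusionMatrix, MetricsReport, SeedSummary, confusion,
                      micro_metrics)
from .featext import RGBNormalizer, make_extractor, slice_scale_bags
from .labels import TissueKind
from .maskops import binarize, concat_channels
from .scat import (ScatClassifier, ScatConfig, SliceFeatures,
                   assign_soft_labels, desk_profile)
from .synthdata import SlideCase, load_case, read_manifest

#: Fixed seed for the fit/validation case split (kept constant across runs).
_SPLIT_SEED = 1234


def case_slice_features(case: SlideCase, tissues: Sequence[TissueKind],
                        scales: Sequence[str], encoder,
                        normalizer: RGBNormalizer) -> List[SliceFeatures]:
    """Per-slice feature dicts {scale: (n_patches, 1280)} for one case."""
    out: List[SliceFeatures] = []
    for i, (rgb, mask) in enumerate(case.slices):
        masks = [binarize(mask, t) for t in tissues]
        image = concat_channels(rgb, masks, [t.value for t in tissues])
        image = normalizer.apply(image)
        bags = slice_scale_bags(image, scales, encoder,
                                provenance={"case_id": case.case_id, "slice": i})
        out.append({name: bag.embeddings for name, bag in bags.items()})
    return out


@dataclass
class FeatureStore:
    """Per-case slice features plus the cases themselves."""

    features: Dict[str, List[SliceFeatures]]
    cases: Dict[str, SlideCase]
    splits: Dict[str, str]                      # case_id -> "train"/"test"
    #: per-scale (mean, sd) used to standardize embeddings
    embed_stats: Dict[str, Tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict)

    def case_ids(self, split: str) -> List[str]:
        return sorted(cid for cid, s in self.splits.items() if s == split)


def build_feature_store(dataset_dir: Union[str, Path],
                        tissues: Sequence[Union[str, TissueKind]],
                        scales: Sequence[str],
                        encoder_seed: int = 0) -> FeatureStore:
    """Load a generated dataset and embed every slice.

    The RGB normalizer is fitted on the training half only; mask channels
    bypass normalization and enter the encoder as {0,1} floats.  Patch
    embeddings are standardized per dimension and scale with
    training-half statistics: a large pretrained backbone emits
    well-conditioned features out of the box, whereas the compact
    randomly initialized encoder does not, and the aggregator's
    optimization depends on that conditioning.
    """
    dataset_dir = Path(dataset_dir)
    manifest = read_manifest(dataset_dir / "manifest.csv")
    tissues = [TissueKind.from_string(t) if isinstance(t, str) else t
               for t in tissues]
    splits = dict(zip(manifest["case_id"], manifest["split"]))
    cases = {cid: load_case(manifest, dataset_dir, cid) for cid in splits}

    train_rgbs = [rgb for cid, case in cases.items() if splits[cid] == "train"
                  for rgb, _ in case.slices]
    normalizer = RGBNormalizer.fit(train_rgbs)
    encoder = make_extractor(3 + len(tissues), seed=encoder_seed)

    features = {cid: case_slice_features(case, tissues, scales, encoder,
                                         normalizer)
                for cid, case in cases.items()}

    embed_stats: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    scale_names = [s if isinstance(s, str) else s.name for s in scales]
    for s in scale_names:
        from .featext import get_scale
        s = get_scale(s).name
        train_emb = np.concatenate(
            [sf[s] for cid in splits if splits[cid] == "train"
             for sf in features[cid]])
        mu = train_emb.mean(axis=0)
        sd = np.maximum(train_emb.std(axis=0), 1e-6)
        embed_stats[s] = (mu, sd)
        for slices in features.values():
            for sf in slices:
                sf[s] = ((sf[s] - mu) / sd).astype(np.float32)
    return FeatureStore(features=features, cases=cases, splits=splits,
                        embed_stats=embed_stats)


def _fit_val_split(case_ids: List[str], cases: Dict[str, SlideCase],
                   val_fraction: float) -> Tuple[List[str], List[str]]:
    """Stratified fit/validation case split with a fixed internal seed."""
    rng = np.random.default_rng(_SPLIT_SEED)
    by_class: Dict[int, List[str]] = {}
    for cid in case_ids:
        by_class.setdefault(int(cases[cid].diagnosis), []).append(cid)
    fit, val = [], []
    for cls in sorted(by_class):
        ids = sorted(by_class[cls])
        n_val = max(1, round(val_fraction * len(ids))) if len(ids) > 1 else 0
        chosen = set(rng.choice(len(ids), size=n_val, replace=False).tolist())
        for i, cid in enumerate(ids):
            (val if i in chosen else fit).append(cid)
    if not val:
        raise ValueError("validation split is empty; need more training cases")
    return fit, val


def _training_arrays(store: FeatureStore, fit_ids: List[str],
                     scales: Sequence[str], strategy: str
                     ) -> Tuple[List[SliceFeatures], np.ndarray, List[str]]:
    X, y_rows, case_of_slice = [], [], []
    ref_scale = scales[0]
    for cid in fit_ids:
        slices = store.features[cid]
        slice_means = np.stack([sf[ref_scale].mean(axis=0) for sf in slices])
        labels = assign_soft_labels(store.cases[cid], slice_means,
                                    strategy=strategy)
        X.extend(slices)
        y_rows.append(labels)
        case_of_slice.extend([cid] * len(slices))
    return X, np.concatenate(y_rows, axis=0), case_of_slice


@dataclass
class SeedRunResult:
    seed: int
    report: MetricsReport
    cm: ConfusionMatrix


@dataclass
class ExperimentResult:
    tissues: Tuple[str, ...]
    scales: Tuple[str, ...]
    summary: SeedSummary
    per_seed: pd.DataFrame
    runs: List[SeedRunResult] = field(default_factory=list)


def run_experiment(dataset_dir: Union[str, Path],
                   tissues: Sequence[Union[str, TissueKind]] = (),
                   scales: Sequence[str] = ("7.5x",),
                   seeds: Sequence[int] = (0,),
                   config: Optional[ScatConfig] = None,
                   val_fraction: float = 0.25,
                   soft_label_strategy: str = "svd",
                   encoder_seed: int = 0,
                   store: Optional[FeatureStore] = None,
                   out_dir: Optional[Union[str, Path]] = None
                   ) -> ExperimentResult:
    """Train and score one tissue-mask experiment over several seeds.

    For each seed: train the aggregator on the fit cases' slices (soft
    labels), average the best five checkpoints by validation micro F,
    predict every test slice, max-vote to case diagnoses and score with
    micro-averaged metrics.  Returns the seed summary (average/min/max/
    median micro F, mean sensitivity/specificity) and the per-seed table;
    optionally writes the summary-table CSV and confusion matrices.
    """
    seeds = list(seeds)
    if not seeds:
        raise ValueError("at least one seed is required")
    base_cfg = config or desk_profile()
    scales = tuple(base_cfg.scales) if config else tuple(scales)
    if config is None:
        base_cfg = desk_profile(scales=scales)
    if store is None:
        store = build_feature_store(dataset_dir, tissues, scales,
                                    encoder_seed=encoder_seed)

    fit_ids, val_ids = _fit_val_split(store.case_ids("train"), store.cases,
                                      val_fraction)
    X, y, case_of_slice = _training_arrays(store, fit_ids, scales,
                                           soft_label_strategy)
    val_cases = {cid: store.features[cid] for cid in val_ids}
    val_labels = {cid: store.cases[cid].diagnosis for cid in val_ids}
    test_ids = store.case_ids("test")
    reference = [store.cases[cid].diagnosis for cid in test_ids]

    runs, rows = [], []
    for seed in seeds:
        cfg = ScatConfig(**{**_cfg_dict(base_cfg), "seed": seed})
        clf = ScatClassifier(config=cfg)
        clf.fit(X, y, train_case_ids=case_of_slice, val_cases=val_cases,
                val_labels=val_labels)
        predicted = [clf.predict_case(store.features[cid]) for cid in test_ids]
        cm = confusion(reference, predicted)
        report = micro_metrics(cm)
        runs.append(SeedRunResult(seed=seed, report=report, cm=cm))
        rows.append({"seed": seed, "micro_f": report.micro_f,
                     "sensitivity": report.sensitivity,
                     "specificity": report.specificity})

    per_seed = pd.DataFrame(rows)
    summary = SeedSummary(
        per_seed_f=[r.report.micro_f for r in runs],
        mean_sensitivity=float(np.mean([r.report.sensitivity for r in runs])),
        mean_specificity=float(np.mean([r.report.specificity for r in runs])))
    result = ExperimentResult(
        tissues=tuple(TissueKind.from_string(t).value if isinstance(t, str)
                      else t.value for t in tissues),
        scales=scales, summary=summary, per_seed=per_seed, runs=runs)
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _cfg_dict(cfg: ScatConfig) -> dict:
    return {f: getattr(cfg, f) for f in cfg.__dataclass_fields__}


def _write_outputs(result: ExperimentResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    name = "WSI" + "".join(f"+{t}" for t in result.tissues)
    row = {"experiment": name, **result.summary.to_row()}
    pd.DataFrame([row]).to_csv(out_dir / "summary.csv", index=False)
    result.per_seed.to_csv(out_dir / "per_seed.csv", index=False)
    for run in result.runs:
        run.cm.to_frame().to_csv(out_dir / f"confusion_seed{run.seed}.csv")


def summary_table(results: Iterable[ExperimentResult]) -> pd.DataFrame:
    """Combine experiments into one summary table (one row per experiment)."""
    rows = []
    for res in results:
        name = "WSI" + "".join(f"+{t}" for t in res.tissues)
        rows.append({"experiment": name, **res.summary.to_row()})
    return pd.DataFrame(rows)
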