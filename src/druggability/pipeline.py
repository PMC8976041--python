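"""End-to-end orchestration: load or simulate sequences, gate by length,
encode, select, train, cross-validate, and write artifacts.

A single :class:`RunConfig` (loadable from YAML) drives everything; a
provenance manifest (config echo, seed, package versions) is written so
a run can be reproduced from its output directory alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .encoders import DEFAULT_ENCODERS, EncoderSpec, encode_dataset
from .evaluation import MetricsReport, cross_validate
from .feat_select import DEFAULT_SUPERSET_KS, select_superset
from .models import ModelConfig, save_bundle, train
from .seq_io import LabeledDataset, load_labeled, write_feature_csv
from .synthetic import SyntheticConfig, generate

logger = logging.getLogger("druggability")


@dataclass(frozen=True)
class RunConfig:
    """Everything a full run needs, in one place."""

    pos_fasta: str | None = None
    neg_fasta: str | None = None
    synthetic: SyntheticConfig | None = None
    sanitize_policy: str = "skip"
    min_length: int = 50
    encoders: tuple[str, ...] = DEFAULT_ENCODERS
    encoder_params: tuple[tuple[str, Any], ...] = ()  # lam, w, n_seg
    selection_ks: tuple[tuple[str, int], ...] | None = tuple(
        DEFAULT_SUPERSET_KS.items()
    )
    selection_scope: str = "per_fold"
    selection_step: int = 1
    model: ModelConfig = field(default_factory=ModelConfig)
    cv_folds: int = 10
    seed: int = 42
    out_dir: str = "runs/latest"

    def __post_init__(self) -> None:
        have_files = self.pos_fasta is not None and self.neg_fasta is not None
        if not have_files and self.synthetic is None:
            raise ValueError("config needs pos/neg FASTA paths or a synthetic block")
        unknown = set(self.encoders) - {"aac", "gdpc", "raaa", "pseaac", "s_pseaac"}
        if unknown:
            raise ValueError(f"unknown encoders: {sorted(unknown)}")
        if self.selection_scope not in ("per_fold", "global"):
            raise ValueError("selection_scope must be 'per_fold' or 'global'")

    @property
    def pse_params(self) -> dict[str, Any]:
        return dict(self.encoder_params)

    def encoder_specs(self) -> list[EncoderSpec]:
        p = self.pse_params
        specs = []
        for name in self.encoders:
            if name in ("pseaac", "s_pseaac"):
                kwargs = {k: p[k] for k in ("lam", "w") if k in p}
                if name == "s_pseaac" and "n_seg" in p:
                    kwargs["n_seg"] = p["n_seg"]
                specs.append(EncoderSpec.make(name, **kwargs))
            else:
                specs.append(EncoderSpec.make(name))
        return specs

    def as_dict(self) -> dict[str, Any]:
        return {
            "pos_fasta": self.pos_fasta,
            "neg_fasta": self.neg_fasta,
            "synthetic": self.synthetic.as_dict() if self.synthetic else None,
            "sanitize_policy": self.sanitize_policy,
            "min_length": self.min_length,
            "encoders": list(self.encoders),
            "encoder_params": dict(self.encoder_params),
            "selection_ks": dict(self.selection_ks) if self.selection_ks else None,
            "selection_scope": self.selection_scope,
            "selection_step": self.selection_step,
            "model": self.model.as_dict(),
            "cv_folds": self.cv_folds,
            "seed": self.seed,
            "out_dir": self.out_dir,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if d.get("synthetic"):
            syn = dict(d["synthetic"])
            if "enriched_set" in syn:
                syn["enriched_set"] = frozenset(syn["enriched_set"])
            if syn.get("background"):
                syn["background"] = tuple(syn["background"])
            d["synthetic"] = SyntheticConfig(**syn)
        if d.get("model"):
            m = dict(d["model"])
            extra = {
                k: m.pop(k)
                for k in list(m)
                if k
                not in (
                    "algorithm",
                    "n_estimators",
                    "eta",
                    "max_depth",
                    "reg_lambda",
                    "reg_alpha",
                    "seed",
                    "n_jobs",
                )
            }
            d["model"] = ModelConfig(**m, extra=tuple(sorted(extra.items())))
        for key in ("encoders",):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("encoder_params"):
            d["encoder_params"] = tuple(sorted(d["encoder_params"].items()))
        if d.get("selection_ks"):
            d["selection_ks"] = tuple(d["selection_ks"].items())
        return cls(**{k: v for k, v in d.items() if v is not None or k in ("selection_ks",)})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def feasible_min_length(config: RunConfig) -> int:
    """Smallest sequence length every configured encoder can accept.

    Segmented PseAAC needs every segment longer than lambda, i.e. length
    >= n_seg * (lam + 1); the configured gate is auto-raised to that
    bound with a warning when set lower.
    """
    bound = 2  # dipeptide encoders need length >= 2
    if "s_pseaac" in config.encoders or "pseaac" in config.encoders:
        p = config.pse_params
        lam = int(p.get("lam", 5))
        n_seg = int(p.get("n_seg", 2)) if "s_pseaac" in config.encoders else 1
        bound = max(bound, n_seg * (lam + 1))
    if config.min_length < bound:
        logger.warning(
            "min_length %d below encoder feasibility bound %d; raised",
            config.min_length,
            bound,
        )
        return bound
    return config.min_length


def length_gate(
    data: LabeledDataset, min_length: int
) -> tuple[LabeledDataset, list[str]]:
    """Drop records shorter than min_length; returns the kept dataset and
    the ids of dropped records."""
    keep = [i for i, r in enumerate(data.records) if len(r.sequence) >= min_length]
    dropped = [r.id for i, r in enumerate(data.records) if i not in set(keep)]
    if not keep:
        raise ValueError(f"all records shorter than min_length={min_length}")
    logger.info("length gate removed %d record(s)", len(dropped))
    return (
        LabeledDataset(
            records=[data.records[i] for i in keep], labels=data.labels[keep]
        ),
        dropped,
    )


def _load_input(config: RunConfig) -> tuple[LabeledDataset, dict]:
    if config.synthetic is not None:
        return generate(config.synthetic), {"source": "synthetic"}
    data, log = load_labeled(
        config.pos_fasta, config.neg_fasta, policy=config.sanitize_policy
    )
    return data, {"source": "fasta", "sanitation": log.as_dict()}


def run(config: RunConfig) -> MetricsReport:
    """Execute the full method and write artifacts under config.out_dir:
    feature matrix CSV, selection results, a model trained on all data,
    the cross-validation MetricsReport (JSON + CSV) and a provenance
    manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    data, input_log = _load_input(config)
    gate = feasible_min_length(config)
    data, dropped = length_gate(data, gate)

    specs = config.encoder_specs()
    full = encode_dataset(data, specs)
    write_feature_csv(full.X, full.labels, out / "features.csv")

    selection_ks = dict(config.selection_ks) if config.selection_ks else None

    report = cross_validate(
        data,
        specs,
        model_config=config.model,
        selection_ks=selection_ks,
        selection_scope=config.selection_scope,
        selection_step=config.selection_step,
        k=config.cv_folds,
        seed=config.seed,
    )
    report.to_json(out / "metrics.json")
    report.to_csv(
        out / "metrics.csv",
        classifier=config.model.algorithm,
        descriptor="+".join(config.encoders),
    )

    # final model on all data (selection, if any, on the full matrix)
    if selection_ks:
        per_encoder = {}
        for spec in specs:
            fm = encode_dataset(data, [spec])
            per_encoder[spec.name] = (fm, selection_ks.get(spec.name, fm.shape[1]))
        final_fm, sel_results = select_superset(
            per_encoder,
            seed=config.seed,
            step=config.selection_step,
            config=config.model,
        )
        for name, res in sel_results.items():
            res.to_json(out / f"selection_{name}.json")
    else:
        final_fm = full
    bundle = train(final_fm.X, final_fm.labels, config.model.with_seed(config.seed))
    save_bundle(bundle, out / "model.joblib")

    manifest = {
        "package_version": __version__,
        "config": config.as_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.as_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "input": input_log,
        "length_gate": {"min_length": gate, "dropped": dropped},
        "n_samples": len(data),
        "n_features_full": full.shape[1],
        "summary": report.summary,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report


def run_benchmark_grid(
    config: RunConfig,
    algorithms: tuple[str, ...] = ("ert", "rf", "xgb"),
    descriptors: tuple[str, ...] = ("raaa", "gdpc", "s_pseaac", "all"),
):
    """Classifier x descriptor benchmark grid (one summary row each),
    shaped like the published before/after-selection tables."""
    import pandas as pd

    from .evaluation import METRIC_NAMES

    rows = []
    for algo in algorithms:
        for desc in descriptors:
            encoders = tuple(DEFAULT_ENCODERS) if desc == "all" else (desc,)
            sub = replace(
                config,
                encoders=encoders,
                model=replace(config.model, algorithm=algo),
                out_dir=str(Path(config.out_dir) / f"{algo}_{desc}"),
            )
            report = run(sub)
            summary = report.summary
            row = {"classifier": algo.upper(), "feature_descriptor": desc}
            for m in METRIC_NAMES:
                mean = summary[m]["mean"]
                row[m] = None if mean is None else round(mean, 4)
            rows.append(row)
    df = pd.DataFrame(rows)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "benchmark_grid.csv", index=False)
    return df
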