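"""Config-driven orchestration: simulate → quantify → stats from one YAML file.

A run directory receives stage outputs (cohort TIFFs + manifest, metric
CSVs, statistics JSON) plus a provenance record with the seed, thresholds
and package version, so a run is reproducible from its config alone.
All randomness funnels through the single configured seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import glia as gl
from . import stats as st
from . import synapses as sy
from .geometry import get_scheme, read_stack
from .studies import (
    _focal_plaque,
    _sub_seed,
    glia_scene,
    quantify_glia_cohort,
    synapse_scene,
)
from .synthetic import generate_cohort
from .qpcr import fold_change, group_summary

VALID_MODES = ("simulate", "quantify-synapses", "quantify-glia", "qpcr", "stats", "all")


@dataclass
class RunConfig:
    """Validated run configuration (plain YAML key/value)."""

    mode: str = "all"
    out_dir: str = "runs/demo"
    seed: int = 0
    assay: str = "synapse"  # synapse | glia
    scheme: str = "synapse_excitatory"
    n_per_group: int = 2
    n_slices: int = 1
    n_images_per_slice: int = 1
    deficit: dict = field(default_factory=lambda: {"0-10": 0.5})
    ct_csv: str | None = None
    control_group: str = "WT"

    def __post_init__(self) -> None:
        if self.mode not in VALID_MODES:
            raise ValueError(f"mode must be one of {VALID_MODES}, got {self.mode!r}")
        get_scheme(self.scheme)  # must name an existing preset
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _write_provenance(out: Path, config: RunConfig, extra: dict | None = None) -> None:
    prov = {"package_version": __version__, "config": asdict(config)}
    prov.update(extra or {})
    (out / "provenance.json").write_text(json.dumps(prov, indent=2, default=str))


def stage_simulate(config: RunConfig) -> Path:
    out = Path(config.out_dir) / "cohort"
    if config.assay == "synapse":
        wt, tg = synapse_scene("WT"), synapse_scene("NLGF", deficit=config.deficit)
    else:
        wt, tg = glia_scene("WT"), glia_scene("NLGF")
    generate_cohort(
        wt, tg, config.n_per_group, config.seed, out,
        n_slices=config.n_slices, n_images_per_slice=config.n_images_per_slice,
    )
    return out


def _read_cohort(cohort_dir: Path):
    manifest = pd.read_csv(cohort_dir / "manifest.csv")
    for _, row in manifest.iterrows():
        meta = {k: row[k] for k in ("animal", "genotype", "age", "slice", "image")}
        yield meta, read_stack(row.path), None


def stage_quantify_synapses(config: RunConfig) -> Path:
    cohort_dir = Path(config.out_dir) / "cohort"
    rows = []
    for idx, (meta, stack, _t) in enumerate(_read_cohort(cohort_dir)):
        plaque = _focal_plaque(stack, reference_radius_um=8.0)
        df = sy.quantify_image_synapses(
            stack, plaque, direction_seed=_sub_seed(config.seed, 7, idx),
            scheme=config.scheme,
        )
        for _, r in df.iterrows():
            rows.append({**meta, **r.to_dict()})
    per_image = pd.DataFrame(rows)
    table = sy.synapse_density_table(per_image, scheme=config.scheme)
    out = Path(config.out_dir) / "synapse_metrics.csv"
    table.to_csv(out, index=False)
    return out


def stage_quantify_glia(config: RunConfig) -> Path:
    cohort_dir = Path(config.out_dir) / "cohort"
    per_image = quantify_glia_cohort(_read_cohort(cohort_dir), scheme="microglia_10um")
    table = gl.glia_metric_table(per_image)
    out = Path(config.out_dir) / "glia_metrics.csv"
    table.to_csv(out, index=False)
    return out


def stage_qpcr(config: RunConfig) -> Path:
    if not config.ct_csv:
        raise ValueError("qpcr stage requires ct_csv in the config")
    ct = pd.read_csv(config.ct_csv)
    folds = fold_change(ct, control_group=config.control_group)
    out_dir = Path(config.out_dir)
    folds.to_csv(out_dir / "fold_changes.csv", index=False)
    group_summary(folds).to_csv(out_dir / "fold_change_summary.csv", index=False)
    return out_dir / "fold_changes.csv"


def stage_stats(config: RunConfig) -> Path:
    metrics_csv = Path(config.out_dir) / (
        "synapse_metrics.csv" if config.assay == "synapse" else "glia_metrics.csv"
    )
    table = pd.read_csv(metrics_csv)
    scheme = get_scheme(config.scheme if config.assay == "synapse" else "microglia_10um")
    bin_order = scheme.bin_labels if config.assay == "synapse" else scheme.labels
    results = {}
    if config.assay == "synapse":
        res = st.factorial_distance_test(table, bin_order)
        results["synapse_density"] = res.to_dict()
    else:
        for metric, sub in table.groupby("metric"):
            res = st.factorial_distance_test(sub, bin_order)
            results[str(metric)] = res.to_dict()
    out = Path(config.out_dir) / "stats.json"
    out.write_text(json.dumps(results, indent=2, default=float))
    return out


def run(config: RunConfig) -> Path:
    """Execute the configured stage(s); returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    quantify = stage_quantify_synapses if config.assay == "synapse" else stage_quantify_glia
    stages = {
        "simulate": (stage_simulate,),
        "quantify-synapses": (stage_quantify_synapses,),
        "quantify-glia": (stage_quantify_glia,),
        "qpcr": (stage_qpcr,),
        "stats": (stage_stats,),
        "all": (stage_simulate, quantify, stage_stats),
    }
    for fn in stages[config.mode]:
        try:
            fn(config)
        except Exception as exc:  # stage-tagged failure
            raise RuntimeError(f"stage {fn.__name__} failed: {exc}") from exc
    _write_provenance(out, config)
    return out
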