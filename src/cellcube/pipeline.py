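"""End-to-end pipeline: validate -> preprocess -> aggregate (+ roll-up) -> markers.

A run is driven by a single :class:`RunConfig`; all randomness flows from its
one seed, stages execute in a fixed order with no stage reading a later
stage's outputs, and the effective configuration plus per-stage bookkeeping
is echoed into the output directory as ``manifest.json``. Re-running with
the same config and inputs reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from anndata import AnnData

from . import io as cio
from .aggregate import CubePart, build_cube, cube_rollup
from .markers import compute_markers_all
from .ontology import OntologyGraph
from .preprocess import PreprocessConfig, run_preprocess
from .schema import SchemaConfig, check_primary_uniqueness, validate_dataset
from .synth import SynthConfig, generate_corpus

logger = logging.getLogger("cellcube")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Parameters of one pipeline run (fully serializable)."""

    input_dir: str | None = None  # None: generate a synthetic corpus
    out_dir: str = "cellcube_run"
    seed: int = 0
    group_by: tuple[str, ...] = ()
    do_rollup: bool = True
    ontology_path: str | None = None
    marker_k: int = 25
    marker_reps: int = 100
    marker_variant: str = "welch"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw = dict(raw)
        if "preprocess" in raw and isinstance(raw["preprocess"], dict):
            raw["preprocess"] = _sub(PreprocessConfig, raw["preprocess"])
        if "synth" in raw and isinstance(raw["synth"], dict):
            raw["synth"] = _sub(SynthConfig, raw["synth"])
        if "group_by" in raw:
            raw["group_by"] = tuple(raw["group_by"])
        return cls(**raw)

    def to_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (frozenset, set)):
                return sorted(map(clean, obj))
            if isinstance(obj, (tuple, list)):
                return [clean(v) for v in obj]
            if isinstance(obj, Path):
                return str(obj)
            return obj

        return clean(self)


def _sub(cls, raw: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    if cls is PreprocessConfig and "assay_allowlist" in raw:
        raw = dict(raw, assay_allowlist=frozenset(raw["assay_allowlist"]))
    if cls is SynthConfig:
        for key in ("tissues", "labeled_types"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "cell_type_tree" in raw:
            raw["cell_type_tree"] = tuple(tuple(e) for e in raw["cell_type_tree"])
    return cls(**raw)


def load_corpus(input_dir: str | Path) -> list[AnnData]:
    """Read every dataset in a directory (``*.h5ad`` and MTX-triplet subdirs)."""
    input_dir = Path(input_dir)
    datasets = []
    for p in sorted(input_dir.glob("*.h5ad")):
        datasets.append(cio.read_dataset(p, "h5ad"))
    for p in sorted(d for d in input_dir.iterdir() if d.is_dir()):
        if (p / "matrix.mtx").exists():
            datasets.append(cio.read_dataset(p, "mtx_triplet"))
    if not datasets:
        raise FileNotFoundError(f"no datasets found under {input_dir}")
    return datasets


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline and return the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": []}

    # ---- inputs
    graph: OntologyGraph | None = None
    try:
        if config.input_dir is None:
            synth_cfg = dataclasses.replace(config.synth, seed=config.seed)
            corpus = generate_corpus(synth_cfg)
            datasets = corpus.datasets
            graph = corpus.graph
        else:
            datasets = load_corpus(config.input_dir)
        if config.ontology_path is not None:
            graph = cio.read_ontology(config.ontology_path)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("inputs", exc) from exc

    # ---- stage 1: validate
    try:
        reports = [validate_dataset(d, SchemaConfig()) for d in datasets]
        primary = check_primary_uniqueness(datasets)
        all_ok = all(r.passed for r in reports) and primary.passed
        (out / "validation.json").write_text(
            json.dumps(
                {
                    "passed": all_ok,
                    "datasets": [r.to_dict() for r in reports],
                    "primary_uniqueness": primary.to_dict(),
                },
                indent=1,
            )
        )
        if not all_ok:
            raise ValueError("corpus failed schema validation (see validation.json)")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("validate", exc) from exc
    manifest["stages"].append("validate")

    # ---- stage 2: preprocess
    try:
        results = run_preprocess(datasets, config.preprocess)
        for name, res in results.items():
            logger.info(
                "%s: removed %s; %d cells retained",
                name,
                res.removed,
                len(res.retained),
            )
        manifest["removed"] = {n: r.removed for n, r in results.items()}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("preprocess", exc) from exc
    manifest["stages"].append("preprocess")

    # ---- stage 3: aggregate (+ roll-up)
    try:
        parts = [
            CubePart(
                normalized=res.normalized,
                metadata=d.obs.iloc[res.retained],
                genes=list(d.var_names),
            )
            for d, res in zip(datasets, results.values())
        ]
        cube = build_cube(parts, group_by=config.group_by)
        cio.write_cube(cube, out / "cube.tsv")
        if config.do_rollup:
            if graph is None:
                raise ValueError("roll-up requested but no ontology available")
            cio.write_cube(cube_rollup(cube, graph), out / "cube_rollup.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("aggregate", exc) from exc
    manifest["stages"].append("aggregate")

    # ---- stage 4: markers
    try:
        table = compute_markers_all(
            parts,
            k=config.marker_k,
            reps=config.marker_reps,
            seed=config.seed,
            variant=config.marker_variant,
        )
        cio.write_markers(table, out / "markers.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("markers", exc) from exc
    manifest["stages"].append("markers")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
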