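"""End-to-end pipeline: simulate -> features -> render -> embed -> classify -> report.

One global seed determines every stochastic output, and every stage writes
only inside the configured output directory.  A manifest JSON lists each
artifact with its SHA-256, the config hash, and the seed; rerunning with
the same config reproduces the classification CSV and the manifest hash
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from spikesight.embedding import load_encoder
from spikesight.fewshot import (
    SupportSet,
    build_prototypes,
    classify_query,
    embed_records,
)
from spikesight.imaging import RenderConfig
from spikesight.synthetic import synth_population
from spikesight.validation import (
    DEFAULT_REFERENCE_TABLE,
    check_plausibility,
    compute_type_proportions,
    export_results,
    load_reference_table,
)


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one pipeline run."""

    out_dir: str
    seed: int = 0
    n_per_type: int = 20
    separation_level: str = "separable"
    types: tuple = ("Pyramidal", "SST", "GABA_nonSST", "Juxtacellular")
    k_shots: int = 8
    encoder_backend: str = "mock_projection"
    embedding_dim: int = 64
    temperature: float = 1.0
    unknown_threshold: float = 0.0
    region: str = "cortex"
    reference_table_path: str | None = None
    image_size: tuple = (224, 224)

    def validate(self) -> None:
        if self.k_shots < 1:
            raise ValueError("k_shots must be >= 1")
        if not 0 <= self.unknown_threshold < 1:
            raise ValueError("unknown_threshold must be in [0, 1)")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.n_per_type <= self.k_shots:
            raise ValueError("n_per_type must exceed k_shots")

    def hash(self) -> str:
        # out_dir is a run location, not a scientific parameter: keep the hash
        # stable across output directories
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the simulate -> classify -> report pipeline; return the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    log_lines = []

    def log(stage, msg):
        log_lines.append(f"[{stage}] t={time.time() - t0:.2f}s config={config.hash()} {msg}")

    # stage 1: synthetic population
    records = synth_population(
        n_per_type=config.n_per_type,
        separation_level=config.separation_level,
        seed=config.seed,
        types=config.types,
    )
    log("simulate", f"generated {len(records)} labeled units")

    # stage 2: render + embed
    encoder = load_encoder(
        {"backend": config.encoder_backend, "dim": config.embedding_dim, "seed": config.seed}
    )
    render_cfg = RenderConfig(image_size=config.image_size)
    embeddings = embed_records(records, encoder, render_cfg)
    log("embed", f"embedded {len(embeddings)} panels (dim={config.embedding_dim})")

    # stage 3: K-shot support sampling + classification of the remainder
    rng = np.random.default_rng(config.seed)
    by_class: dict = {}
    for i, r in enumerate(records):
        by_class.setdefault(r.label, []).append(i)
    support_idx: dict = {}
    for label in sorted(by_class):
        idx = np.asarray(by_class[label])
        if idx.size <= config.k_shots:
            raise ValueError(f"insufficient support for class {label!r}")
        support_idx[label] = rng.choice(idx, size=config.k_shots, replace=False)
    support = SupportSet(
        {label: [embeddings[i] for i in chosen] for label, chosen in support_idx.items()}
    )
    prototypes = build_prototypes(support)
    chosen_all = {int(i) for chosen in support_idx.values() for i in chosen}
    results = []
    for i, r in enumerate(records):
        if i in chosen_all:
            continue
        res = classify_query(
            embeddings[i], prototypes, config.temperature, config.unknown_threshold
        )
        results.append((r.unit_id, res))
    results.sort(key=lambda pair: str(pair[0]))
    classification_csv = export_results(results, out / "classifications.csv", fmt="csv")
    log("classify", f"classified {len(results)} query units with K={config.k_shots}")

    # stage 4: proportions + plausibility report
    labels = [res.predicted_label for _, res in results]
    proportions = compute_type_proportions(labels)
    reference = (
        load_reference_table(config.reference_table_path)
        if config.reference_table_path
        else DEFAULT_REFERENCE_TABLE
    )
    report = check_plausibility(proportions, reference, region=config.region)
    report_json = export_results([report], out / "plausibility.json", fmt="json")
    log("report", f"overall_flag={report.overall_flag}")

    artifacts = {
        p.name: _sha256(p) for p in (classification_csv, report_json)
    }
    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config.hash(),
        "seed": config.seed,
        "artifacts": artifacts,
    }
    stable = {k: v for k, v in manifest.items() if k != "config"}
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(stable, sort_keys=True, default=str).encode()
    ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return manifest
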