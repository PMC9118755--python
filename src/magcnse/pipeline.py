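"""End-to-end orchestration: simulate -> similarity -> embed -> classify -> evaluate.

``run_pipeline`` executes the full chain on one run directory, writing every
intermediate as TSV plus a JSON manifest (config, fanned-out seeds, package
versions, config hash) sufficient to reproduce the run bit-for-bit on the
same platform.  A single top-level seed fans out to per-stage seeds by
fixed offsets so stages stay independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ensemble import EnsembleConfig
from .evaluation import CvPlan, cross_validate, summarize_cv
from .io_formats import (
    read_associations,
    read_fasta,
    read_ontology,
    write_associations,
    write_fasta,
    write_matrix,
    write_ontology,
)
from .representation import GcnConfig, train_representations
from .similarity import (
    disease_semantic_similarity,
    gip_similarity,
    lncrna_functional_similarity,
    lncrna_sequence_similarity,
)
from .synthetic_data import SyntheticConfig, generate_dataset

__all__ = ["RunConfig", "run_pipeline", "SEED_OFFSETS"]

# fixed fan-out of the top-level seed to the stochastic stages
SEED_OFFSETS = {"synthetic": 0, "representation": 101, "pairs": 202, "ensemble": 303, "cv": 404}


@dataclass
class RunConfig:
    """Flat configuration of one pipeline run."""

    out_dir: str = "magcnse_run"
    seed: int = 0
    simulate: bool = True
    associations: str | None = None
    fasta: str | None = None
    ontology: str | None = None
    # synthetic data
    n_lncrna: int = 100
    n_disease: int = 50
    n_blocks: int = 4
    p_in: float = 0.3
    p_out: float = 0.01
    seq_len: int = 200
    mutation_rate: float = 0.1
    # representation learning
    embedding_size: int = 128
    num_layers: int = 2
    n_filters: int = 128
    learning_rate: float = 0.001
    epochs: int = 250
    ablation: str = "none"  # none | fgl | natt | nattcnn | ncnn
    paper_faithful: bool = False
    # ensemble + evaluation
    ensemble_profile: str = "reference"  # reference | compact
    cv_folds: int = 5
    cv_repeats: int = 5

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a flat key=value config file (``#`` comments allowed)."""
        values: dict[str, object] = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value")
                key, raw = (part.strip() for part in line.split("=", 1))
                if key not in fields:
                    raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
                values[key] = _coerce(raw, fields[key].type)
        return cls(**values)

    def gcn_config(self) -> GcnConfig:
        flags = {
            "none": {},
            "fgl": {"first_layer_only": True},
            "natt": {"use_attention": False},
            "nattcnn": {"use_attention": False, "use_cnn": False},
            "ncnn": {"use_cnn": False},
        }
        if self.ablation not in flags:
            raise ValueError(f"unknown ablation {self.ablation!r}")
        return GcnConfig(
            embedding_size=self.embedding_size,
            num_layers=self.num_layers,
            n_filters=self.n_filters,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            seed=self.seed + SEED_OFFSETS["representation"],
            leakage_safe=not self.paper_faithful,
            **flags[self.ablation],
        )

    def ensemble_config(self) -> EnsembleConfig:
        seed = self.seed + SEED_OFFSETS["ensemble"]
        if self.ensemble_profile == "reference":
            return EnsembleConfig.reference(seed=seed)
        if self.ensemble_profile == "compact":
            return EnsembleConfig.compact(seed=seed)
        raise ValueError(f"unknown ensemble profile {self.ensemble_profile!r}")


def _coerce(raw: str, annotation) -> object:
    text = str(annotation)
    if "bool" in text:
        if raw.lower() in ("true", "1", "yes", "on"):
            return True
        if raw.lower() in ("false", "0", "no", "off"):
            return False
        raise ValueError(f"cannot parse boolean from {raw!r}")
    if "int" in text:
        return int(raw)
    if "float" in text:
        return float(raw)
    return raw


def compute_views(ld, seqs, dag):
    """All five similarity views from the three inputs, canonical order."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dss = disease_semantic_similarity(dag, ld.disease_ids)
        lfs = lncrna_functional_similarity(ld, dss)
    lss = lncrna_sequence_similarity(seqs, ld.lncrna_ids)
    lgs = gip_similarity(ld, "lncrna")
    dgs = gip_similarity(ld, "disease")
    return [lfs, lss, lgs], [dss, dgs]


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "simulate" if cfg.simulate else "load-inputs"
    try:
        if cfg.simulate:
            syn = SyntheticConfig(
                n_lncrna=cfg.n_lncrna,
                n_disease=cfg.n_disease,
                n_blocks=cfg.n_blocks,
                p_in=cfg.p_in,
                p_out=cfg.p_out,
                seq_len=cfg.seq_len,
                mutation_rate=cfg.mutation_rate,
                seed=cfg.seed + SEED_OFFSETS["synthetic"],
            )
            ld, seqs, dag, _ = generate_dataset(syn)
            write_associations(out / "associations.tsv", ld)
            write_fasta(out / "sequences.fasta", seqs)
            write_ontology(out / "ontology.tsv", dag)
        else:
            if not (cfg.associations and cfg.fasta and cfg.ontology):
                raise ValueError("associations, fasta and ontology paths are required")
            ld = read_associations(cfg.associations)
            seqs = read_fasta(cfg.fasta)
            dag = read_ontology(cfg.ontology)

        stage = "similarity"
        views_l, views_d = compute_views(ld, seqs, dag)
        for view in (*views_l, *views_d):
            write_matrix(
                out / f"similarity_{view.view_name.lower()}.tsv",
                view.values,
                view.entity_ids,
                view.entity_ids,
            )

        stage = "embed"
        gcn_cfg = cfg.gcn_config()
        x, y, trace = train_representations(views_l, views_d, ld, gcn_cfg)
        write_matrix(
            out / "lncrna_embeddings.tsv",
            x.values,
            [f"f{i}" for i in range(x.values.shape[0])],
            x.entity_ids,
        )
        write_matrix(
            out / "disease_embeddings.tsv",
            y.values,
            [f"f{i}" for i in range(y.values.shape[0])],
            y.entity_ids,
        )
        pd.DataFrame({"epoch": np.arange(len(trace.values)), "loss": trace.values}).to_csv(
            out / "loss_trace.tsv", sep="\t", index=False
        )

        stage = "evaluate"
        plan = CvPlan(k=cfg.cv_folds, repeats=cfg.cv_repeats, seed=cfg.seed + SEED_OFFSETS["cv"])
        table = cross_validate(ld, views_d[0], views_l[1], plan, gcn_cfg, cfg.ensemble_config())
        table.to_csv(out / "cv_folds.tsv", sep="\t", index=False)
        summarize_cv(table).to_frame("mean").to_csv(out / "cv_summary.tsv", sep="\t")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    config_dict = dataclasses.asdict(cfg)
    manifest = {
        "magcnse_version": __version__,
        "numpy_version": np.__version__,
        "config": config_dict,
        "config_hash": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "stage_seeds": {k: cfg.seed + v for k, v in SEED_OFFSETS.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
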