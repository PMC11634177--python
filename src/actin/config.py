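"""Run configuration: schema-validated YAML with filled defaults.

A single YAML file configures the whole pipeline; unknown keys and type
mismatches are rejected with the offending key path.  An empty file yields
all defaults.  Every artifact a run writes embeds the resolved config hash
and seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .expression import StepFunctionParams
from .model import DrugEncoderConfig, InterfusionConfig, ModelConfig
from .synthdata import DEFAULT_PREVALENCE, PlantedEffect, SynthConfig
from .training import SplitSpec, TrainConfig


class ConfigError(ValueError):
    """Raised for invalid run configuration files."""


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class StepFunctionSection(_Section):
    inner_gain: float = 1.0
    inner_weight: float = 0.1
    outer_gain: float = 1.0
    threshold: float = 1.0


class EncoderSection(_Section):
    atom_embed_dim: int = 256
    gat_heads: int = 4
    gat_head_dim: int = 64
    pool_ratio: float = 0.8
    n_stages: int = 2
    leaky_slope: float = 0.2


class InterfusionSection(_Section):
    d: int = 256
    d_k: int = 64
    heads: int = 4
    n_blocks: int = 6
    ffn_hidden: int = 1024


class TrainingSection(_Section):
    batch_size: int = Field(default=1000, ge=1)
    epochs: int = Field(default=50, ge=1)
    lr: float = Field(default=1e-3, gt=0)
    patience: int = Field(default=10, ge=1)
    seed: int = 0
    beta: float = Field(default=1.0, gt=0)
    split: list[float] = Field(default_factory=lambda: [0.8, 0.2])

    @field_validator("split")
    @classmethod
    def _check_split(cls, v):
        if len(v) not in (2, 3) or abs(sum(v) - 1.0) > 1e-9:
            raise ValueError("split must be 2 or 3 fractions summing to 1")
        return v


class EffectSection(_Section):
    element: str
    target_genes: list[int]
    beta: float
    direction: int = 1


class SynthSection(_Section):
    n_drugs: int = 200
    n_genes: int = 100
    noise_sd: float = 0.3
    seed: int = 42
    cell_line: str = "SYN1"
    min_atoms: int = 8
    max_atoms: int = 20
    ring_prob: float = 0.3
    ppi_mean_degree: float = 6.0
    element_prevalence: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    effects: list[EffectSection] = Field(
        default_factory=lambda: [EffectSection(element="S", target_genes=list(range(20)), beta=2.5)]
    )


class RunConfig(_Section):
    step_function: StepFunctionSection = Field(default_factory=StepFunctionSection)
    encoder: EncoderSection = Field(default_factory=EncoderSection)
    interfusion: InterfusionSection = Field(default_factory=InterfusionSection)
    training: TrainingSection = Field(default_factory=TrainingSection)
    synth: SynthSection = Field(default_factory=SynthSection)
    gene_dim: int = 128

    # -- conversions to the runtime dataclasses ---------------------------
    def sf_params(self) -> StepFunctionParams:
        s = self.step_function
        return StepFunctionParams(inner_gain=s.inner_gain, inner_weight=s.inner_weight,
                                  outer_gain=s.outer_gain, threshold=s.threshold)

    def model_cfg(self) -> ModelConfig:
        return ModelConfig(
            encoder=DrugEncoderConfig(**self.encoder.model_dump()),
            interfusion=InterfusionConfig(**self.interfusion.model_dump()),
            gene_dim=self.gene_dim,
        )

    def train_cfg(self, seed: int | None = None) -> TrainConfig:
        t = self.training
        use_seed = t.seed if seed is None else seed
        return TrainConfig(batch_size=t.batch_size, epochs=t.epochs, lr=t.lr,
                           patience=t.patience, seed=use_seed, beta=t.beta,
                           split=SplitSpec(tuple(t.split), seed=use_seed),
                           sf_params=self.sf_params())

    def synth_cfg(self, seed: int | None = None) -> SynthConfig:
        s = self.synth
        return SynthConfig(
            n_drugs=s.n_drugs, n_genes=s.n_genes,
            element_prevalence=dict(s.element_prevalence), noise_sd=s.noise_sd,
            effects=[PlantedEffect(element=e.element, target_genes=frozenset(e.target_genes),
                                   beta=e.beta, direction=e.direction) for e in s.effects],
            seed=s.seed if seed is None else seed, cell_line=s.cell_line,
            min_atoms=s.min_atoms, max_atoms=s.max_atoms, ring_prob=s.ring_prob,
        )

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path=None) -> RunConfig:
    """Load and validate a YAML config; missing file sections get defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ConfigError(f"{path}: {loc}: {first['msg']}") from None


def dump_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
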