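"""Run configuration: a flat, strictly validated, YAML-serializable record.

Every field has either a published default or a documented calibration
default.  Unknown keys in a config file are errors; ``load(save(cfg)) == cfg``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .add_process import DEFAULT_KAPPA, AddConfig
from .connectome import StructuralNetwork, generate_surrogate, load_adjacency
from .neural_mass import NeuralMassParams

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # model constants
    fs: float = 500.0
    epoch_len: int = 4096
    transient_len: int = 5000
    pt: float = 550.0
    noiselevel: float = 1.0
    amp1: float = 1.6
    amp2: float = 32.0
    a1: float = 55.0
    b1: float = 605.0
    a2: float = 27.5
    b2: float = 55.0
    g: float = 25.0
    q: float = 0.34
    vd1: float = 7.0
    vd2: float = 7.0
    c1: float = 32.0
    c2: float = 3.0
    s: float = 1.5
    substeps: int = 2
    noise_sigma: float | None = None
    psp_normalization: str = "raw"
    # degeneration rule
    d: float = 0.01
    kappa: float = DEFAULT_KAPPA
    add_literal: bool = False
    strength_floor: float = 1e-6
    # connectome: explicit path wins over surrogate settings
    connectome_path: str | None = None
    n_nodes: int = 78
    density: float = 0.10
    surrogate_model: str = "modular"
    n_modules: int = 5
    connectome_seed: int = 1
    use_aal_labels: bool = False
    # run structure
    n_epochs: int = 10
    n_runs: int = 20
    seed: int = 42
    # analysis
    measures: list[str] = field(default_factory=lambda: ["AECc", "PLI", "PLT", "JPE"])
    bands: list[str] = field(default_factory=lambda: ["delta", "theta", "alpha", "beta"])
    n_perm: int = 5000
    q_fdr: float = 0.05
    plt_boundary: str = "truncated"
    jpe_literal: bool = False
    edge_trim: float = 0.01
    gamma_high: float = 48.0

    def params(self) -> NeuralMassParams:
        return NeuralMassParams(
            fs=self.fs,
            epoch_len=self.epoch_len,
            transient_len=self.transient_len,
            pt=self.pt,
            noiselevel=self.noiselevel,
            amp1=self.amp1,
            amp2=self.amp2,
            a1=self.a1,
            b1=self.b1,
            a2=self.a2,
            b2=self.b2,
            g=self.g,
            q=self.q,
            vd1=self.vd1,
            vd2=self.vd2,
            c1=self.c1,
            c2=self.c2,
            s=self.s,
            substeps=self.substeps,
            noise_sigma=self.noise_sigma,
            psp_normalization=self.psp_normalization,
        )

    def add_config(self) -> AddConfig:
        return AddConfig(
            d=self.d, kappa=self.kappa, literal=self.add_literal, floor=self.strength_floor
        )

    def network(self) -> StructuralNetwork:
        if self.connectome_path:
            net = load_adjacency(self.connectome_path)
        else:
            net = generate_surrogate(
                self.n_nodes,
                self.density,
                model=self.surrogate_model,
                seed=self.connectome_seed,
                n_modules=self.n_modules,
            )
        if self.use_aal_labels:
            from .connectome import aal78_labels

            labels = aal78_labels()
            if net.n_nodes != len(labels):
                raise ValueError("AAL-78 labels require a 78-node network")
            net.labels = labels
        return net

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
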