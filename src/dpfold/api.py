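"""High-level assembly: map a FoldConfig onto a concrete strategy and run it."""

from __future__ import annotations

from typing import Optional

from .core import FoldConfig, RnaSequence
from .engine import FoldStrategy, PredictionResult
from .errors import DomainError
from .helix import HelixStrategy
from .nussinov import NussinovStrategy
from .partition import predict_partition
from .zuker import EnergyModel, ZukerStrategy, default_energy_model, load_energy_model
from . import engine


def resolve_energy_model(cfg: FoldConfig) -> EnergyModel:
    if cfg.energy_params:
        return load_energy_model(cfg.energy_params)
    return default_energy_model()


def make_strategy(cfg: FoldConfig, em: Optional[EnergyModel] = None) -> FoldStrategy:
    """Instantiate the strategy selected by ``cfg.algorithm``."""
    if cfg.algorithm == "nussinov":
        return NussinovStrategy()
    em = em or resolve_energy_model(cfg)
    if cfg.algorithm == "zuker":
        return ZukerStrategy(em)
    if cfg.algorithm == "helix":
        return HelixStrategy(em)
    if cfg.algorithm == "partition":
        from .partition import PartitionStrategy

        return PartitionStrategy(em)
    raise DomainError(f"unknown algorithm {cfg.algorithm!r}")


def predict(
    seq: RnaSequence, cfg: Optional[FoldConfig] = None, em: Optional[EnergyModel] = None
) -> PredictionResult:
    """Run the configured strategy on one validated sequence."""
    cfg = cfg or FoldConfig()
    if cfg.algorithm == "partition":
        # the partition wrapper adds overflow-rescale retries
        return predict_partition(seq, cfg, em or resolve_energy_model(cfg))
    return engine.run(seq, make_strategy(cfg, em), cfg)
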