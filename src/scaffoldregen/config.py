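"""Run configuration: every tunable of the coupled simulation in one
serializable object, with YAML round-trip and a stable content hash."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace

import yaml

from .agents import CellRates
from .mechanoreg import StimulusThresholds, Tissue


@dataclass(frozen=True)
class TissueProperties:
    """Linear-elastic constants per deposited tissue type plus scaffold.

    Granulation and scaffold values are the model's anchor points
    (0.2 MPa / 0.167 and 1000 MPa / 0.3); fibrous tissue, cartilage and
    bone follow the fracture-healing model lineage and are calibration
    parameters.  Moduli in MPa.
    """

    E: dict[int, float] = field(
        default_factory=lambda: {
            int(Tissue.GRANULATION): 0.2,
            int(Tissue.FIBROUS_TISSUE): 2.0,
            int(Tissue.CARTILAGE): 10.0,
            int(Tissue.BONE): 1000.0,
        }
    )
    nu: dict[int, float] = field(
        default_factory=lambda: {
            int(Tissue.GRANULATION): 0.167,
            int(Tissue.FIBROUS_TISSUE): 0.167,
            int(Tissue.CARTILAGE): 0.167,
            int(Tissue.BONE): 0.3,
        }
    )
    scaffold_E: float = 1000.0
    scaffold_nu: float = 0.3

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.E.values()) or self.scaffold_E <= 0:
            raise ValueError("all moduli must be positive")
        if self.E[int(Tissue.GRANULATION)] != min(self.E.values()):
            raise ValueError("granulation must be the softest tissue")


@dataclass(frozen=True)
class SimulationConfig:
    """Everything that defines one regeneration run except the design.

    ``element_size`` (mm) sets the FE voxel size; ``sites_per_element``
    the agent sub-lattice (5 gives the nominal 20 um spacing at 0.1 mm
    elements); ``days`` the number of daily iterations; ``window`` the
    tissue-maturation averaging length in days.
    """

    element_size: float = 0.1
    sites_per_element: int = 5
    days: int = 60
    force: float = 15.0
    load_surface: str = "scaffold"      # "scaffold" | "full"
    seeding_occupancy: float = 0.30
    window: int = 10
    porosity_resolution: float = 0.025
    thresholds: StimulusThresholds = field(default_factory=StimulusThresholds)
    rates: CellRates = field(default_factory=CellRates)
    tissues: TissueProperties = field(default_factory=TissueProperties)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            d["thresholds"] = StimulusThresholds(**d["thresholds"])
        if "rates" in d and isinstance(d["rates"], dict):
            r = dict(d["rates"])
            if "proliferation" in r:
                r["proliferation"] = {int(k): v for k, v in r["proliferation"].items()}
            d["rates"] = CellRates(**r)
        if "tissues" in d and isinstance(d["tissues"], dict):
            t = dict(d["tissues"])
            for key in ("E", "nu"):
                if key in t:
                    t[key] = {int(k): v for k, v in t[key].items()}
            d["tissues"] = TissueProperties(**t)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path_or_text) -> "SimulationConfig":
        try:
            with open(path_or_text) as fh:
                text = fh.read()
        except (OSError, TypeError):
            text = path_or_text
        return cls.from_dict(yaml.safe_load(text))

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)
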