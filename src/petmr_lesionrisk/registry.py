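"""The pinned radiomics feature registry.

The feature vector of a lesion has exactly 446 named entries: 442
registry radiomics features plus the four conventional PET uptake
metrics (SUV_max, SUV_peak, SUV_mean, SUV_TLG).  The registry breakdown
is this package's own pinned default:

================  ==========================================  =====
family            features                                    count
================  ==========================================  =====
INTENSITY_STATS   first-order statistics                      18
INTENSITY_HIST    discretized-histogram statistics            23
GLCM (d=1, d=2)   co-occurrence, merged 13 directions         2 x 25
GLRLM             run length, merged 13 directions            16
GLSZM             size zones, 26-connectivity                 16
GLDZM             distance zones (Chebyshev border distance)  16
NGTDM             neighbourhood grey tone difference          5
================  ==========================================  =====

i.e. 144 features per modality (PSMA-PET, ADC, T2w) = 432, plus 10
mask-only morphology features computed once, totalling 442.  The
registry is ordered, versioned, serializable to JSON and
user-overridable.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

from .grids import Modality

__all__ = ["FeatureFamily", "FeatureRegistry", "build_default_registry"]

REGISTRY_VERSION = "1.0"


class FeatureFamily(str, enum.Enum):
    INTENSITY_STATS = "INTENSITY_STATS"
    INTENSITY_HISTOGRAM = "INTENSITY_HISTOGRAM"
    GLCM = "GLCM"
    GLRLM = "GLRLM"
    GLSZM = "GLSZM"
    GLDZM = "GLDZM"
    NGTDM = "NGTDM"
    MORPHOLOGY = "MORPHOLOGY"


STAT_NAMES = ("mean", "var", "skew", "kurt", "median", "min", "p10", "p90", "max",
              "iqr", "range", "mad", "rmad", "medad", "cov", "qcod", "energy", "rms")

HIST_NAMES = ("mean", "var", "skew", "kurt", "median", "min", "p10", "p90", "max",
              "mode", "iqr", "range", "mad", "rmad", "medad", "cov", "qcod",
              "entropy", "uniformity", "max_grad", "max_grad_g", "min_grad", "min_grad_g")

GLCM_NAMES = ("joint_max", "joint_avg", "joint_var", "joint_entr", "diff_avg",
              "diff_var", "diff_entr", "sum_avg", "sum_var", "sum_entr", "energy",
              "contrast", "dissimilarity", "inv_diff", "inv_diff_norm",
              "inv_diff_mom", "inv_diff_mom_norm", "inv_var", "corr", "auto_corr",
              "clust_tend", "clust_shade", "clust_prom", "info_corr_1", "info_corr_2")

GLRLM_NAMES = ("sre", "lre", "lgre", "hgre", "srlge", "srhge", "lrlge", "lrhge",
               "glnu", "glnu_norm", "rlnu", "rlnu_norm", "r_perc", "gl_var",
               "rl_var", "rl_entr")

GLSZM_NAMES = ("sze", "lze", "lgze", "hgze", "szlge", "szhge", "lzlge", "lzhge",
               "glnu", "glnu_norm", "zsnu", "zsnu_norm", "z_perc", "gl_var",
               "zs_var", "zs_entr")

GLDZM_NAMES = ("sde", "lde", "lgze", "hgze", "sdlge", "sdhge", "ldlge", "ldhge",
               "glnu", "glnu_norm", "zdnu", "zdnu_norm", "z_perc", "gl_var",
               "zd_var", "zd_entr")

NGTDM_NAMES = ("coarseness", "contrast", "busyness", "complexity", "strength")

MORPH_NAMES = ("volume_ml", "surface_area_mm2", "surface_to_volume", "compactness_1",
               "compactness_2", "sphericity", "asphericity", "max_diameter_3d",
               "elongation", "flatness")

SUV_NAMES = ("suv_max", "suv_peak", "suv_mean", "suv_tlg")

_MOD_PREFIX = {Modality.PSMA_PET: "pet", Modality.ADC: "adc", Modality.T2W: "t2w"}


@dataclass(frozen=True)
class RegistryEntry:
    modality: Modality | None  # None for mask-only morphology
    family: FeatureFamily
    name: str  # e.g. "cm_d1_info_corr_1"

    @property
    def full_name(self) -> str:
        prefix = "morph" if self.modality is None else _MOD_PREFIX[self.modality]
        return f"{prefix}_{self.name}"


@dataclass
class FeatureRegistry:
    """Ordered, versioned list of radiomics feature entries."""

    entries: tuple[RegistryEntry, ...]
    bins: dict[Modality, int] = field(default_factory=lambda: {m: 32 for m in Modality})
    version: str = REGISTRY_VERSION

    def __post_init__(self) -> None:
        names = [e.full_name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("registry entries are not unique")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(e.full_name for e in self.entries)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "bins": {m.value: b for m, b in self.bins.items()},
            "entries": [[e.modality.value if e.modality else None, e.family.value, e.name]
                        for e in self.entries],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureRegistry":
        payload = json.loads(Path(path).read_text())
        entries = tuple(RegistryEntry(Modality(m) if m else None, FeatureFamily(f), n)
                        for m, f, n in payload["entries"])
        bins = {Modality(m): int(b) for m, b in payload["bins"].items()}
        return cls(entries, bins, payload["version"])


def build_default_registry(bins: int = 32) -> FeatureRegistry:
    """The pinned 442-entry default registry (see module docstring)."""
    entries: list[RegistryEntry] = []
    for modality in (Modality.PSMA_PET, Modality.ADC, Modality.T2W):
        for n in STAT_NAMES:
            entries.append(RegistryEntry(modality, FeatureFamily.INTENSITY_STATS, f"stat_{n}"))
        for n in HIST_NAMES:
            entries.append(RegistryEntry(modality, FeatureFamily.INTENSITY_HISTOGRAM, f"ih_{n}"))
        for dist in (1, 2):
            for n in GLCM_NAMES:
                entries.append(RegistryEntry(modality, FeatureFamily.GLCM, f"cm_d{dist}_{n}"))
        for n in GLRLM_NAMES:
            entries.append(RegistryEntry(modality, FeatureFamily.GLRLM, f"rlm_{n}"))
        for n in GLSZM_NAMES:
            entries.append(RegistryEntry(modality, FeatureFamily.GLSZM, f"szm_{n}"))
        for n in GLDZM_NAMES:
            entries.append(RegistryEntry(modality, FeatureFamily.GLDZM, f"dzm_{n}"))
        for n in NGTDM_NAMES:
            entries.append(RegistryEntry(modality, FeatureFamily.NGTDM, f"ngt_{n}"))
    for n in MORPH_NAMES:
        entries.append(RegistryEntry(None, FeatureFamily.MORPHOLOGY, n))
    registry = FeatureRegistry(tuple(entries), {m: bins for m in Modality})
    assert len(registry) == 442, f"default registry has {len(registry)} entries"
    return registry
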