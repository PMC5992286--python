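"""Pipeline configuration: a validated, YAML-round-trippable record.

Every run writes its resolved configuration next to its outputs so that
results are reproducible from the artifacts alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Sequence

import yaml

from .bands import DEFAULT_BANDS, BandSpec

_ROI_REPRESENTATIONS = ("pca", "centroid")
_ESTIMATORS = ("plv", "iplv", "corr_env")
_ROUTES = ("edge", "tensor", "mpc")
_SCHEMES = ("loocv", "5fold")


@dataclass
class PipelineConfig:
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    fs: float = 250.0
    epoch_len_s: float = 4.0
    epochs: int = 20
    n_rois: int = 20
    n_subjects_per_group: int = 25
    roi_representation: str = "pca"
    estimator: str = "iplv"
    routes: tuple[str, ...] = ("edge",)
    cv_schemes: tuple[str, ...] = ("5fold",)
    cfc_symmetrize: str = "max"
    k_rank: int = 15
    m_consensus: int = 15
    d1: int = 6
    d2: int = 6
    snr: float = 3.0
    noise_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.bands:
            raise ValueError("config field 'bands' must list at least two bands")
        for b in self.bands:
            if not isinstance(b, BandSpec):
                raise ValueError("config field 'bands' entries must be BandSpec")
            if b.hi >= self.fs / 2:
                raise ValueError(
                    f"config field 'bands': band {b.name!r} exceeds Nyquist for fs={self.fs}"
                )
        _check_choice("roi_representation", self.roi_representation, _ROI_REPRESENTATIONS)
        _check_choice("estimator", self.estimator, _ESTIMATORS)
        for r in self.routes:
            _check_choice("routes", r, _ROUTES)
        for s in self.cv_schemes:
            _check_choice("cv_schemes", s, _SCHEMES)
        for name in ("fs", "epoch_len_s", "snr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name!r} must be positive")
        for name in ("epochs", "n_rois", "n_subjects_per_group", "k_rank", "m_consensus", "d1", "d2"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"config field {name!r} must be a positive integer")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bands"] = [{"name": b.name, "lo": b.lo, "hi": b.hi} for b in self.bands]
        d["routes"] = list(self.routes)
        d["cv_schemes"] = list(self.cv_schemes)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "bands" in d:
            bands = []
            for i, bd in enumerate(d["bands"]):
                missing = {"name", "lo", "hi"} - set(bd)
                if missing:
                    raise ValueError(
                        f"config field 'bands[{i}]' is missing {sorted(missing)}"
                    )
                bands.append(BandSpec(bd["lo"], bd["hi"], bd["name"]))
            d["bands"] = tuple(bands)
        for key in ("routes", "cv_schemes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, dict):
            raise ValueError(f"config file {path} does not contain a mapping")
        return cls.from_dict(d)

    def with_overrides(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


def _check_choice(field_name: str, value: str, allowed: Sequence[str]) -> None:
    if value not in allowed:
        raise ValueError(
            f"config field {field_name!r}: {value!r} not in {tuple(allowed)}"
        )
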