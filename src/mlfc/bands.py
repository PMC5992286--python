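"""Frequency-band definitions and the enumeration of coupling modes.

The classical electrophysiological filterbank used throughout the package
splits 0.5-45 Hz into seven canonical rhythms (delta through low gamma).
Intra-frequency coupling is estimated within each band; cross-frequency
coupling (CFC) is estimated for every ordered low->high band pair, giving
7 + C(7,2) = 28 coupling modes in total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal


@dataclass(frozen=True, order=True)
class BandSpec:
    """A frequency band [lo, hi] in Hz.

    Parameters
    ----------
    name : str
        Band label, e.g. ``"alpha1"``.
    lo, hi : float
        Band edges in Hz, ``0 < lo < hi``.
    """

    lo: float
    hi: float
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(
                f"invalid band {self.name!r}: need 0 < lo < hi, got "
                f"lo={self.lo}, hi={self.hi}"
            )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.name}({self.lo}-{self.hi} Hz)"


#: The default seven-band filterbank (Hz).
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec(0.5, 4.0, "delta"),
    BandSpec(4.0, 8.0, "theta"),
    BandSpec(8.0, 10.0, "alpha1"),
    BandSpec(10.0, 13.0, "alpha2"),
    BandSpec(13.0, 20.0, "beta1"),
    BandSpec(20.0, 30.0, "beta2"),
    BandSpec(30.0, 45.0, "gamma1"),
)

#: Greek display labels for the default bands.
GREEK = {
    "delta": "δ",
    "theta": "θ",
    "alpha1": "α₁",
    "alpha2": "α₂",
    "beta1": "β₁",
    "beta2": "β₂",
    "gamma1": "γ₁",
}


@dataclass(frozen=True)
class CouplingMode:
    """One of the 28 coupling modes: a band (intra) or an ordered band pair.

    For cross-frequency modes ``bands`` is ordered (low, high): the first
    band is the modulating (slower) rhythm, the second the modulated
    (faster) one.
    """

    kind: Literal["intra", "cross"]
    bands: tuple[BandSpec, ...]

    def __post_init__(self) -> None:
        if self.kind == "intra":
            if len(self.bands) != 1:
                raise ValueError("intra mode takes exactly one band")
        elif self.kind == "cross":
            if len(self.bands) != 2:
                raise ValueError("cross mode takes exactly two bands")
            lf, hf = self.bands
            if not lf.lo < hf.lo:
                raise ValueError(
                    f"cross mode bands must be ordered low->high, got "
                    f"{lf} before {hf}"
                )
        else:
            raise ValueError(f"unknown mode kind {self.kind!r}")

    @property
    def label(self) -> str:
        return ":".join(b.name for b in self.bands)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.kind}[{self.label}]"


def coupling_modes(bands: Iterable[BandSpec] = DEFAULT_BANDS) -> list[CouplingMode]:
    """Enumerate all coupling modes in fixed order: intra first (band order),
    then cross pairs in lexicographic band-index order.

    With the default 7 bands this yields 7 intra + 21 cross = 28 modes.
    """
    bands = tuple(bands)
    modes = [CouplingMode("intra", (b,)) for b in bands]
    for i in range(len(bands)):
        for j in range(i + 1, len(bands)):
            modes.append(CouplingMode("cross", (bands[i], bands[j])))
    return modes


def band_by_name(name: str, bands: Iterable[BandSpec] = DEFAULT_BANDS) -> BandSpec:
    for b in bands:
        if b.name == name:
            return b
    raise KeyError(f"no band named {name!r}")
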