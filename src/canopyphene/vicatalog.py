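"""Registry of published vegetation indices computed from band reflectances.

Each entry records the index name, the trait family it proxies (canopy
structure, chlorophyll, water status or accessory pigments), the wavelengths
(nm) it requires, the formula, the literature source of the formula, and the
variance-stabilising transform applied in the statistics layer (never to the
stored index values).

The catalog is data: wavelengths follow each index's original publication and
can be overridden by registering a replacement entry.  Published wavelengths
are resolved to the nearest instrument band within a 5 nm tolerance, because a
204-band 400–1000 nm grid does not contain exact integer wavelengths.

Sources are abbreviated: RJ74 Rouse et al. 1974; GM96/GM97 Gitelson &
Merzlyak; H02/H04 Haboudane et al.; R94 Roujean & Breon; CL96 Chen; R96
Rondeaux et al.; H88 Huete; Q94 Qi et al.; HU02 Huete et al. (EVI); BL95
Broge & Leblanc; D98 Datt 1998; K01 Kim/Daughtry (MCARI/TCARI lineage); G02
Gitelson et al. 2002/2003 (ARI, CRI, CI); Z95 Zarco-Tejada/Zhou; V93
Vogelmann et al.; B92 Blackburn 1998 (PSSR); P95 Peñuelas et al. (WBI, NPCI,
SIPI); M99 Merzlyak et al. (PSRI); G96 Gamon et al. (PRI); Z96 Zhou/G (RGI,
G greenness ratio); GA (catalog default, documented choice).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["ViEntry", "ViCatalog", "default_catalog"]


@dataclass(frozen=True)
class ViEntry:
    """One vegetation-index definition.

    ``formula`` receives a resolver ``r`` mapping wavelength (nm) to
    reflectance (scalar or array) and, for range-mean indices, ``rmean``
    mapping an (lo, hi) nm window to the mean reflectance over it.
    """

    name: str
    family: str  # structure | chlorophyll | water | pigment
    wavelengths: tuple[float, ...]
    formula: Callable
    source: str
    transform: str = "none"  # none | log | sqrt | reciprocal
    ranges: tuple[tuple[float, float], ...] = ()
    scale_invariant: bool = False

    def evaluate(self, resolver: Callable, range_resolver: Callable | None = None):
        if self.ranges:
            return self.formula(resolver, range_resolver)
        return self.formula(resolver)

    def evaluate_spectrum(self, wavelengths: np.ndarray, spectrum: np.ndarray):
        """Evaluate on a single spectrum, nearest-band resolution (5 nm)."""
        wavelengths = np.asarray(wavelengths, float)
        spectrum = np.asarray(spectrum, float)

        def r(wl: float):
            i = int(np.argmin(np.abs(wavelengths - wl)))
            if abs(wavelengths[i] - wl) > 5.0:
                raise ValueError(f"{self.name}: no band within 5 nm of {wl} nm")
            return spectrum[i]

        def rmean(window):
            lo, hi = window
            m = (wavelengths >= lo) & (wavelengths <= hi)
            if not m.any():
                raise ValueError(f"{self.name}: no bands in {lo}-{hi} nm")
            return spectrum[m].mean()

        return float(self.evaluate(r, rmean))

    def evaluate_cube(self, cube) -> np.ndarray:
        """Evaluate per pixel on a SpectralCube, returning an index map."""

        def r(wl: float):
            return cube.band(wl)

        def rmean(window):
            lo, hi = window
            m = (cube.wavelengths >= lo) & (cube.wavelengths <= hi)
            if not m.any():
                raise ValueError(f"{self.name}: no bands in {lo}-{hi} nm")
            return cube.values[:, :, m].mean(axis=2)

        with np.errstate(divide="ignore", invalid="ignore"):
            return np.asarray(self.evaluate(r, rmean), dtype=float)


class ViCatalog:
    """Name → ViEntry registry with validation and iteration."""

    def __init__(self, entries: list[ViEntry] | None = None):
        self._entries: dict[str, ViEntry] = {}
        for e in entries or []:
            self.register(e)

    def register(self, entry: ViEntry, replace: bool = False) -> None:
        if entry.name in self._entries and not replace:
            raise ValueError(f"duplicate index name {entry.name!r}")
        self._entries[entry.name] = entry

    def __getitem__(self, name: str) -> ViEntry:
        try:
            return self._entries[name]
        except KeyError:
            raise KeyError(f"unknown vegetation index {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    @property
    def names(self) -> list[str]:
        return list(self._entries)

    def required_wavelengths(self) -> set[float]:
        out: set[float] = set()
        for e in self:
            out.update(e.wavelengths)
        return out


def _nd(a, b):
    """Normalized difference (a − b)/(a + b)."""
    return (a - b) / (a + b)


def default_catalog() -> ViCatalog:
    """The 41-index default catalog used throughout the pipeline."""
    E = ViEntry
    entries = [
        # ---- structure ------------------------------------------------
        E("NDVI", "structure", (800, 670),
          lambda r: _nd(r(800), r(670)), "RJ74", scale_invariant=True),
        E("gNDVI", "structure", (800, 550),
          lambda r: _nd(r(800), r(550)), "GM96", scale_invariant=True),
        E("RDVI", "structure", (800, 670),
          lambda r: (r(800) - r(670)) / np.sqrt(r(800) + r(670)), "R94"),
        E("SR", "structure", (800, 670),
          lambda r: r(800) / r(670), "RJ74", transform="log", scale_invariant=True),
        E("MSR", "structure", (800, 670),
          lambda r: (r(800) / r(670) - 1) / np.sqrt(r(800) / r(670) + 1), "CL96"),
        E("OSAVI", "structure", (800, 670),
          lambda r: 1.16 * (r(800) - r(670)) / (r(800) + r(670) + 0.16), "R96"),
        E("SAVI", "structure", (800, 670),
          lambda r: 1.5 * (r(800) - r(670)) / (r(800) + r(670) + 0.5), "H88"),
        E("MSAVI", "structure", (800, 670),
          lambda r: 0.5 * (2 * r(800) + 1
                           - np.sqrt((2 * r(800) + 1) ** 2
                                     - 8 * (r(800) - r(670)))), "Q94"),
        E("EVI", "structure", (800, 670, 475),
          lambda r: 2.5 * (r(800) - r(670))
          / (r(800) + 6 * r(670) - 7.5 * r(475) + 1), "HU02"),
        E("TVI", "structure", (750, 670, 550),
          lambda r: 0.5 * (120 * (r(750) - r(550)) - 200 * (r(670) - r(550))),
          "BL95"),
        E("MTVI1", "structure", (800, 670, 550),
          lambda r: 1.2 * (1.2 * (r(800) - r(550)) - 2.5 * (r(670) - r(550))),
          "H04"),
        E("MTVI2", "structure", (800, 670, 550),
          lambda r: 1.5 * (1.2 * (r(800) - r(550)) - 2.5 * (r(670) - r(550)))
          / np.sqrt((2 * r(800) + 1) ** 2
                    - (6 * r(800) - 5 * np.sqrt(r(670))) - 0.5), "H04"),
        E("MCARI2", "structure", (800, 670, 550),
          lambda r: 1.5 * (2.5 * (r(800) - r(670)) - 1.3 * (r(800) - r(550)))
          / np.sqrt((2 * r(800) + 1) ** 2
                    - (6 * r(800) - 5 * np.sqrt(r(670))) - 0.5), "H04"),
        E("RGI", "structure", (690, 550),
          lambda r: r(690) / r(550), "Z95", scale_invariant=True),
        E("RGRI", "structure", (),
          lambda r, rm: rm((600, 699)) / rm((500, 599)), "G02",
          ranges=((600, 699), (500, 599)), scale_invariant=True),
        E("G", "structure", (554, 677),
          lambda r: r(554) / r(677), "Z95", scale_invariant=True),
        # ---- chlorophyll ----------------------------------------------
        E("MCARI", "chlorophyll", (700, 670, 550),
          lambda r: ((r(700) - r(670)) - 0.2 * (r(700) - r(550)))
          * (r(700) / r(670)), "K01", transform="sqrt"),
        E("TCARI", "chlorophyll", (700, 670, 550),
          lambda r: 3 * ((r(700) - r(670))
                         - 0.2 * (r(700) - r(550)) * (r(700) / r(670))), "H02"),
        E("TCARI_OSAVI", "chlorophyll", (800, 700, 670, 550),
          lambda r: (3 * ((r(700) - r(670))
                          - 0.2 * (r(700) - r(550)) * (r(700) / r(670))))
          / (1.16 * (r(800) - r(670)) / (r(800) + r(670) + 0.16)), "H02"),
        E("PSSRa", "chlorophyll", (800, 680),
          lambda r: r(800) / r(680), "B92", transform="log", scale_invariant=True),
        E("PSSRb", "chlorophyll", (800, 635),
          lambda r: r(800) / r(635), "B92", transform="log", scale_invariant=True),
        E("PSSRc", "chlorophyll", (800, 470),
          lambda r: r(800) / r(470), "B92", transform="log", scale_invariant=True),
        E("SRChl", "chlorophyll", (860, 708, 550),
          lambda r: r(860) / (r(550) * r(708)), "D98", transform="log"),
        E("SRChlb", "chlorophyll", (750, 700),
          lambda r: r(750) / r(700), "GM97", transform="log", scale_invariant=True),
        E("SRChltot", "chlorophyll", (760, 550),
          lambda r: r(760) / r(550), "GM97", transform="log", scale_invariant=True),
        E("NDRE", "chlorophyll", (750, 705),
          lambda r: _nd(r(750), r(705)), "GM96", scale_invariant=True),
        E("CIrededge", "chlorophyll", (800, 720),
          lambda r: r(800) / r(720) - 1, "G02", scale_invariant=True),
        E("CIgreen", "chlorophyll", (800, 550),
          lambda r: r(800) / r(550) - 1, "G02", scale_invariant=True),
        E("ZM", "chlorophyll", (750, 710),
          lambda r: r(750) / r(710), "Z95", scale_invariant=True),
        E("VOG1", "chlorophyll", (740, 720),
          lambda r: r(740) / r(720), "V93", scale_invariant=True),
        E("GM1", "chlorophyll", (750, 550),
          lambda r: r(750) / r(550), "GM97", scale_invariant=True),
        # ---- water ----------------------------------------------------
        E("WBI", "water", (900, 970),
          lambda r: r(900) / r(970), "P95", scale_invariant=True),
        E("WCI", "water", (900, 680, 550),
          lambda r: (r(900) - r(680)) / (r(900) + r(550)), "GA",
          transform="reciprocal", scale_invariant=True),
        # ---- pigment ---------------------------------------------------
        E("PRI", "pigment", (531, 570),
          lambda r: _nd(r(531), r(570)), "G96", scale_invariant=True),
        E("NPCI", "pigment", (680, 430),
          lambda r: _nd(r(680), r(430)), "P95", scale_invariant=True),
        E("SIPI", "pigment", (800, 680, 445),
          lambda r: (r(800) - r(445)) / (r(800) - r(680)), "P95",
          scale_invariant=True),
        E("PSRI", "pigment", (750, 680, 500),
          lambda r: (r(680) - r(500)) / r(750), "M99", scale_invariant=True),
        E("ARI1", "pigment", (550, 700),
          lambda r: 1 / r(550) - 1 / r(700), "G02"),
        E("ARI2", "pigment", (800, 550, 700),
          lambda r: r(800) * (1 / r(550) - 1 / r(700)), "G02",
          scale_invariant=True),
        E("CRI2", "pigment", (510, 700),
          lambda r: 1 / r(510) - 1 / r(700), "G02"),
        E("BRI", "pigment", (450, 550),
          lambda r: r(450) / r(550), "GA", scale_invariant=True),
    ]
    catalog = ViCatalog(entries)
    assert len(catalog) == 41
    return catalog
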