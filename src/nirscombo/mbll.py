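"""Modified Beer-Lambert law conversion between optical density and hemoglobin.

Continuous-wave fNIRS measures the change in optical density ΔA(t, λ) at two
near-infrared wavelengths.  Because oxygenated (HbO) and deoxygenated (HbR)
hemoglobin have distinct absorption spectra, the two measurements determine the
two concentration changes through a linear system:

    [ΔcHbO(t)]              [α_HbO(λ1)  α_HbR(λ1)]⁻¹ [ΔA(t, λ1)]
    [ΔcHbR(t)] = 1 / (l·d) ·[α_HbO(λ2)  α_HbR(λ2)]   [ΔA(t, λ2)]

where α are extinction coefficients in μM⁻¹·mm⁻¹, l the emitter-detector
distance in mm and d the unitless differential path-length factor (DPF).
With those units the recovered concentrations are in μM.

The default extinction coefficients for 760/830 nm are taken from the
Gratzer/Cope compiled hemoglobin spectra (the compilation distributed with
most NIRS analysis toolboxes), converted from cm⁻¹·M⁻¹ to μM⁻¹·mm⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OpticalDensity",
    "ExtinctionSpec",
    "HemoSeries",
    "mbll_invert",
    "concentrations_to_od",
    "scale_linearity_check",
    "read_od_csv",
    "write_od_csv",
]

#: Gratzer/Cope extinction coefficients, cm⁻¹·M⁻¹, rows = (760, 830) nm,
#: columns = (HbO, HbR).  1 cm⁻¹·M⁻¹ = 1e-7 μM⁻¹·mm⁻¹.
_GRATZER_760_830_CM_M = np.array(
    [
        [1486.5865, 3843.707],
        [2321.4, 1791.734],
    ]
)
DEFAULT_ALPHA_UM_MM = _GRATZER_760_830_CM_M * 1e-7


@dataclass
class OpticalDensity:
    """Two-wavelength absorbance-change series, shape (time, channels, 2)."""

    values: np.ndarray
    fs: float
    wavelengths_nm: tuple[float, float] = (760.0, 830.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != 2:
            raise ValueError(
                f"optical density must have shape (time, channels, 2), got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("optical density contains non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass
class ExtinctionSpec:
    """Extinction matrix, DPF and source-detector distance for the MBLL.

    ``alpha`` rows index wavelength (λ1, λ2), columns index chromophore
    (HbO, HbR); units μM⁻¹·mm⁻¹.  Default distance is the study geometry of
    2.8 cm; DPF defaults to the common adult-forehead value of 6.
    """

    alpha: np.ndarray = field(default_factory=lambda: DEFAULT_ALPHA_UM_MM.copy())
    dpf: float = 6.0
    distance_mm: float = 28.0

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape != (2, 2):
            raise ValueError("alpha must be a 2x2 matrix (wavelengths x chromophores)")
        if self.dpf <= 0:
            raise ValueError("dpf must be positive")
        if self.distance_mm <= 0:
            raise ValueError("distance_mm must be positive")
        if abs(np.linalg.det(self.alpha)) < 1e-300:
            raise np.linalg.LinAlgError("extinction matrix is singular")

    @property
    def pathlength_mm(self) -> float:
        """Effective optical path l·d in mm."""
        return self.distance_mm * self.dpf


@dataclass
class HemoSeries:
    """ΔcHbO / ΔcHbR concentration changes in μM, shape (time, channels)."""

    hbo: np.ndarray
    hbr: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.hbo = np.atleast_2d(np.asarray(self.hbo, dtype=float))
        self.hbr = np.atleast_2d(np.asarray(self.hbr, dtype=float))
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("hbo and hbr must share shape")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not (np.all(np.isfinite(self.hbo)) and np.all(np.isfinite(self.hbr))):
            raise ValueError("concentration series contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[1]

    @property
    def hbt(self) -> np.ndarray:
        """Total hemoglobin change ΔcHbT = ΔcHbO + ΔcHbR (report convenience only)."""
        return self.hbo + self.hbr

    def chromophore(self, name: str) -> np.ndarray:
        if name == "HbO":
            return self.hbo
        if name == "HbR":
            return self.hbr
        raise KeyError(f"unknown chromophore {name!r} (expected 'HbO' or 'HbR')")


def mbll_invert(od: OpticalDensity, ext: ExtinctionSpec | None = None) -> HemoSeries:
    """Recover ΔcHbO/ΔcHbR (μM) from two-wavelength optical density.

    Solves the 2×2 extinction system per sample and channel; exactly linear in
    the input, so scaling the optical density scales the concentrations.
    """
    if ext is None:
        ext = ExtinctionSpec()
    inv = np.linalg.inv(ext.alpha)
    # values: (T, C, 2) x inv^T: (2, 2) -> concentrations (T, C, 2)
    conc = od.values @ inv.T / ext.pathlength_mm
    return HemoSeries(hbo=conc[..., 0], hbr=conc[..., 1], fs=od.fs)


def concentrations_to_od(
    hemo: HemoSeries,
    ext: ExtinctionSpec | None = None,
    wavelengths_nm: tuple[float, float] = (760.0, 830.0),
) -> OpticalDensity:
    """Forward MBLL: ΔA(t, λj) = l·d · [α_HbO(λj)·ΔcHbO + α_HbR(λj)·ΔcHbR].

    Exact inverse of :func:`mbll_invert` for the same ``ExtinctionSpec``.
    """
    if ext is None:
        ext = ExtinctionSpec()
    conc = np.stack([hemo.hbo, hemo.hbr], axis=-1)  # (T, C, 2)
    od = conc @ ext.alpha.T * ext.pathlength_mm
    return OpticalDensity(values=od, fs=hemo.fs, wavelengths_nm=wavelengths_nm)


def scale_linearity_check(
    od: OpticalDensity, ext: ExtinctionSpec, k: float, rtol: float = 1e-10
) -> bool:
    """True iff mbll_invert(k·od) == k·mbll_invert(od) within tolerance."""
    scaled = OpticalDensity(od.values * k, fs=od.fs, wavelengths_nm=od.wavelengths_nm)
    a = mbll_invert(scaled, ext)
    b = mbll_invert(od, ext)
    atol = 1e-15
    return bool(
        np.allclose(a.hbo, k * b.hbo, rtol=rtol, atol=atol)
        and np.allclose(a.hbr, k * b.hbr, rtol=rtol, atol=atol)
    )


# ---------------------------------------------------------------------------
# CSV/TSV interchange (long format written by nirscombo.synthetic)
# ---------------------------------------------------------------------------

def write_od_csv(path, od: OpticalDensity, subject: int = 0, sep: str = "\t") -> None:
    """Write one recording as long-format TSV: subject, channel, wavelength_nm, time_s, delta_A."""
    t = np.arange(od.n_samples) / od.fs
    frames = []
    for w, wl in enumerate(od.wavelengths_nm):
        for c in range(od.n_channels):
            frames.append(
                pd.DataFrame(
                    {
                        "subject": subject,
                        "channel": c,
                        "wavelength_nm": wl,
                        "time_s": t,
                        "delta_A": od.values[:, c, w],
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def read_od_csv(path, sep: str = "\t") -> OpticalDensity:
    """Read a single-subject long-format optical-density table back into arrays."""
    df = pd.read_csv(path, sep=sep)
    required = {"channel", "wavelength_nm", "time_s", "delta_A"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"optical-density table missing columns: {sorted(missing)}")
    wavelengths = np.sort(df["wavelength_nm"].unique())
    if wavelengths.size != 2:
        raise ValueError(f"expected exactly 2 wavelengths, found {wavelengths.size}")
    channels = np.sort(df["channel"].unique())
    times = np.sort(df["time_s"].unique())
    if times.size < 2:
        raise ValueError("need at least two samples to infer the sampling rate")
    fs = 1.0 / float(np.median(np.diff(times)))
    values = np.empty((times.size, channels.size, 2))
    for w, wl in enumerate(wavelengths):
        for c, ch in enumerate(channels):
            sub = df[(df["wavelength_nm"] == wl) & (df["channel"] == ch)]
            sub = sub.sort_values("time_s")
            if len(sub) != times.size:
                raise ValueError("ragged optical-density table (uneven samples per channel)")
            values[:, c, w] = sub["delta_A"].to_numpy()
    return OpticalDensity(values=values, fs=fs, wavelengths_nm=tuple(wavelengths))
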