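"""Modified Beer-Lambert law: intensities -> optical density -> concentrations.

Continuous-wave fNIRS measures relative light-intensity changes at two
wavelengths (here 760 and 850 nm, one on each side of the hemoglobin
isosbestic point). The differential form of the modified Beer-Lambert law
relates the optical-density change at wavelength lambda to chromophore
concentration changes:

    dOD(lambda) = [eps_HbO2(lambda) dC_HbO2 + eps_HHb(lambda) dC_HHb]
                   * DPF(lambda) * d

with eps the molar extinction coefficients (1/(mM*cm)), d the geometric
source-detector separation (cm) and DPF the differential pathlength factor
accounting for scattering-lengthened photon paths. Two wavelengths give a
2x2 linear system solved per sample for (dC_HbO2, dC_HHb); outputs are µM.

Baseline referencing: dOD is computed against the mean intensity over the
quiet baseline span, so concentrations are changes from baseline. A slow
multiplicative source drift can be removed first (``drift_correct``) by
fitting a linear trend to log-intensity over the baseline only — the task
period never enters the fit, so evoked changes cannot be regressed out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .series import SampledSeries

__all__ = [
    "MBLLParameters",
    "load_extinction_table",
    "drift_correct",
    "intensity_to_od",
    "od_to_concentration",
    "forward_od",
]

_DEFAULT_TABLE = "extinction_hb.txt"


def load_extinction_table(path: str | Path | None = None) -> dict[float, tuple[float, float]]:
    """Read a wavelength -> (eps_HbO2, eps_HHb) table, units 1/(mM*cm).

    ``None`` loads the packaged compiled-hemoglobin tabulation. The file
    format is whitespace-separated columns ``wavelength_nm eps_hbo2
    eps_hhb``; ``#`` starts a comment.
    """
    if path is None:
        text = (resources.files("nirsrls") / "data" / _DEFAULT_TABLE).read_text()
    else:
        text = Path(path).read_text()
    table: dict[float, tuple[float, float]] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        wl, e1, e2 = line.split()
        table[float(wl)] = (float(e1), float(e2))
    if not table:
        raise ValueError("extinction table is empty")
    return table


@dataclass(frozen=True)
class MBLLParameters:
    """Wavelengths, extinction matrix, DPF and separation for one channel.

    ``extinction[i]`` is (eps_HbO2, eps_HHb) at ``wavelengths_nm[i]`` in
    1/(mM*cm); ``dpf`` is the per-wavelength differential pathlength factor
    (default 6.0, a common adult-head convention); ``separation_cm`` the
    geometric source-detector distance.
    """

    separation_cm: float
    wavelengths_nm: tuple[float, float] = (760.0, 850.0)
    extinction: tuple[tuple[float, float], tuple[float, float]] | None = None
    dpf: tuple[float, float] = (6.0, 6.0)

    def __post_init__(self) -> None:
        if self.extinction is None:
            table = load_extinction_table()
            try:
                eps = tuple(table[wl] for wl in self.wavelengths_nm)
            except KeyError as exc:
                raise ValueError(
                    f"no packaged extinction entry at {exc.args[0]} nm; "
                    "pass an explicit extinction matrix"
                ) from None
            object.__setattr__(self, "extinction", eps)
        if self.separation_cm <= 0:
            raise ValueError("separation must be > 0 cm")
        if any(d <= 0 for d in self.dpf):
            raise ValueError("DPF must be > 0")
        mat = np.asarray(self.extinction, dtype=float)
        if mat.shape != (2, 2):
            raise ValueError("extinction must be a 2x2 matrix")
        if np.linalg.cond(mat) > 1e8:
            raise ValueError("extinction matrix is singular or ill-conditioned")

    @property
    def pathlength_matrix(self) -> np.ndarray:
        """2x2 matrix A with dOD = A @ dC(mM): A = diag(DPF*d) @ extinction."""
        eps = np.asarray(self.extinction, dtype=float)
        scale = np.asarray(self.dpf) * self.separation_cm
        return scale[:, None] * eps


def drift_correct(intensity: SampledSeries, baseline_span_s: float) -> SampledSeries:
    """Remove a slow multiplicative source drift estimated from the baseline.

    A straight line is fitted to log10-intensity over the first
    ``baseline_span_s`` seconds; the whole record is divided by the fitted
    relative trend 10**(slope*(t - t_baseline_mean)). A drift-free series is
    returned unchanged (slope 0 -> unit gain).
    """
    n_base = int(round(baseline_span_s * intensity.fs))
    if n_base < 2:
        raise ValueError("baseline span must contain at least 2 samples")
    if n_base > len(intensity):
        raise ValueError("baseline span exceeds the record")
    _check_positive(intensity.values)
    t = intensity.times()
    tb = t[:n_base]
    slope, _ = np.polyfit(tb, np.log10(intensity.values[:n_base]), 1)
    gain = 10.0 ** (slope * (t - tb.mean()))
    return intensity.with_values(intensity.values / gain)


def intensity_to_od(intensity: SampledSeries, baseline_span_s: float) -> SampledSeries:
    """Optical-density change relative to the baseline-mean intensity.

    dOD(t) = -log10( I(t) / mean(I over baseline) ); the mean dOD over the
    baseline span is therefore ~0.
    """
    n_base = int(round(baseline_span_s * intensity.fs))
    if n_base < 1:
        raise ValueError("baseline span must contain at least 1 sample")
    if n_base > len(intensity):
        raise ValueError("baseline span exceeds the record")
    _check_positive(intensity.values)
    i_ref = intensity.values[:n_base].mean()
    return intensity.with_values(-np.log10(intensity.values / i_ref))


def od_to_concentration(
    od760: SampledSeries, od850: SampledSeries, p: MBLLParameters
) -> tuple[SampledSeries, SampledSeries]:
    """Solve the two-wavelength MBLL system for (dHbO2, dHHb) in µM."""
    if not od760.same_clock(od850):
        raise ValueError("the two optical-density series must share length and rate")
    a = p.pathlength_matrix
    od = np.vstack([od760.values, od850.values])  # (2, n)
    conc_mm = np.linalg.solve(a, od)  # mM, per sample
    hbo2 = od760.with_values(1e3 * conc_mm[0])
    hhb = od760.with_values(1e3 * conc_mm[1])
    return hbo2, hhb


def forward_od(
    hbo2: SampledSeries, hhb: SampledSeries, p: MBLLParameters
) -> tuple[SampledSeries, SampledSeries]:
    """Forward MBLL: concentration changes (µM) -> dOD at each wavelength."""
    if not hbo2.same_clock(hhb):
        raise ValueError("the two concentration series must share length and rate")
    a = p.pathlength_matrix
    conc_mm = np.vstack([hbo2.values, hhb.values]) * 1e-3
    od = a @ conc_mm
    return hbo2.with_values(od[0]), hbo2.with_values(od[1])


def _check_positive(values: np.ndarray) -> None:
    bad = np.flatnonzero(values <= 0)
    if bad.size:
        raise ValueError(f"non-positive intensity at index {int(bad[0])}")
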