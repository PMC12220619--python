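"""Standard Normal Variate (SNV) scatter correction.

SNV standardises each spectrum independently — subtract the spectrum's own
mean, divide by its own standard deviation — which removes the per-scan
multiplicative and additive scatter introduced by probe placement and
specimen geometry.  After SNV, every scan is on a common unitless scale and
cohort-level statistics compare spectral *shape* rather than overall level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .spectra_io import ScanSpectrum, WavelengthGrid

__all__ = ["snv_transform", "snv_transform_matrix", "CohortMatrix"]


@dataclass
class CohortMatrix:
    """Pooled SNV spectra for one cohort: scans as rows, wavelengths as columns.

    ``scan_labels`` keeps the (specimen_id, scan_replicate) provenance of
    each row in the deterministic row order (sorted by specimen then
    replicate).
    """

    values: np.ndarray
    scan_labels: list[tuple[str, int]]
    grid: WavelengthGrid

    @property
    def n_scans(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_points(self) -> int:
        return int(self.values.shape[1])


def snv_transform(
    spectrum: Sequence[float] | np.ndarray, ddof: int = 1
) -> np.ndarray:
    """SNV-correct one absorbance vector: ``(x - mean(x)) / sd(x)``.

    ``ddof=1`` (sample standard deviation) is the default; ``ddof=0`` gives
    the population convention.  The downstream outlier fraction is invariant
    to this choice because the per-wavelength quartile fences rescale with
    the data, but intermediate values differ.

    Raises ``ValueError`` for vectors shorter than 2 or with zero spread
    ("degenerate spectrum"), for which SNV is undefined.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("SNV needs a 1-D spectrum with at least 2 points")
    if not np.all(np.isfinite(x)):
        raise ValueError("SNV input contains non-finite values")
    sd = x.std(ddof=ddof)
    if sd == 0:
        raise ValueError("degenerate spectrum: zero variance, SNV undefined")
    return (x - x.mean()) / sd


def snv_transform_matrix(
    scans: Iterable[ScanSpectrum], ddof: int = 1
) -> CohortMatrix:
    """SNV-correct a cohort of scans into a scans x wavelengths matrix.

    Rows are ordered by (specimen_id, scan_replicate) so the result does not
    depend on input order.  A degenerate scan is reported with its specimen
    id.
    """
    ordered = sorted(scans, key=lambda s: (s.specimen_id, s.scan_replicate))
    if not ordered:
        raise ValueError("empty scan collection")
    grid = ordered[0].grid
    if any(s.grid != grid for s in ordered):
        raise ValueError("scans mix wavelength grids")
    rows = []
    for s in ordered:
        try:
            rows.append(snv_transform(s.absorbance, ddof=ddof))
        except ValueError as exc:
            raise ValueError(
                f"specimen {s.specimen_id!r} replicate {s.scan_replicate}: {exc}"
            ) from None
    return CohortMatrix(
        values=np.vstack(rows),
        scan_labels=[(s.specimen_id, s.scan_replicate) for s in ordered],
        grid=grid,
    )
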