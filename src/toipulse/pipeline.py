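"""End-to-end branches tying the modules together.

``toi_branch`` runs video -> bitplane selection -> HC composition -> pulse
extraction -> RRI -> Poincare summary; ``ecg_branch`` runs the reference
waveform through R-peak detection to the same summary.  Both return the
intermediate objects so callers (CLI, tests) can inspect every stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import ecg as ecg_mod
from . import hrv, pulse, toi_extract, videoio


@dataclass
class TOIResult:
    weights: toi_extract.BitplaneWeights
    selection: toi_extract.SelectionReport | None
    roi_name: str
    roi_snr_db: dict[str, float]
    hc: pulse.HCSignal
    peaks: pulse.PeakTrain
    rri: hrv.RRISeries
    summary: hrv.PoincareSummary


@dataclass
class ECGResult:
    peaks: pulse.PeakTrain
    rri: hrv.RRISeries
    summary: hrv.PoincareSummary


def toi_branch(
    stack: videoio.FrameStack,
    roi_map: videoio.ROIMap,
    weights: toi_extract.BitplaneWeights | None = None,
    selection_config: toi_extract.SelectionConfig | None = None,
    roi_name: str | None = None,
    band: tuple[float, float] = pulse.CARDIAC_BAND,
) -> TOIResult:
    """Contactless branch.

    When ``weights`` is None the bitplane selector is run first.  The RRI
    series comes from the single ROI with the highest cardiac-band SNR of
    the composed signal unless ``roi_name`` pins one.
    """
    plane_means = videoio.roi_bitplane_means(stack, roi_map)
    selection = None
    if weights is None:
        cfg = selection_config or toi_extract.SelectionConfig(cardiac_band=band)
        selection = toi_extract.select_bitplane_weights(
            stack, roi_map, cfg, plane_means=plane_means
        )
        if not selection.converged:
            raise ValueError("toi: bitplane selection found no cardiac signal")
        weights = selection.weights

    roi_snr: dict[str, float] = {}
    for name in roi_map.names():
        series = toi_extract.compose_signal(plane_means[name], weights)
        try:
            roi_snr[name] = toi_extract.snr_objective(series, stack.fps, band)
        except (ValueError, toi_extract.DegenerateSignalError):
            roi_snr[name] = float("-inf")
    if roi_name is None:
        roi_name = max(roi_snr, key=lambda k: roi_snr[k])
    hc = pulse.HCSignal(
        values=toi_extract.compose_signal(plane_means[roi_name], weights),
        fps=stack.fps,
        roi_name=roi_name,
    )
    peaks = pulse.extract_peaks(hc, band)
    rri = hrv.rri_from_peaks(peaks)
    summary = hrv.poincare(rri, source="TOI")
    return TOIResult(
        weights=weights, selection=selection, roi_name=roi_name,
        roi_snr_db=roi_snr, hc=hc, peaks=peaks, rri=rri, summary=summary,
    )


def ecg_branch(record: ecg_mod.ECGRecord,
               config: ecg_mod.RPeakConfig | None = None) -> ECGResult:
    """Reference branch: R-peak detection to Poincare summary."""
    peaks = ecg_mod.detect_r_peaks(record, config)
    rri = hrv.rri_from_peaks(peaks)
    summary = hrv.poincare(rri, source="ECG")
    return ECGResult(peaks=peaks, rri=rri, summary=summary)
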