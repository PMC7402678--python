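"""Calcium-motility association and nearest-event latency.

For each extending/retracting process, calcium events with peak
dF/F >= 0.5 are searched for the nearest peak before and after the
motility start; the smaller latency is binned into nested
<30 / <60 / <120 s windows.
"""

from caltrack import bin_latency_fractions, nearest_event_latency
from caltrack.motility import MotilityEvent
from caltrack.traces import CalciumEvent


def ev(peak_frame, peak_dff=1.0, roi="p0"):
    return CalciumEvent(roi, peak_frame - 2, peak_frame + 5, peak_frame,
                        peak_dff, peak_dff * 4)


def mot(roi, start):
    return MotilityEvent(roi, "extension", 12.0, 20.0, 0.66,
                         start_frame=start, end_frame=start + 50)


records = [
    nearest_event_latency([ev(80), ev(150)], mot("p0", 100), frame_rate_hz=1.0),
    nearest_event_latency([ev(55, roi="p1")], mot("p1", 100), 1.0),
    nearest_event_latency([ev(205, roi="p2")], mot("p2", 100), 1.0),
    nearest_event_latency([ev(95, peak_dff=0.4, roi="p3")], mot("p3", 100), 1.0),
]
for r in records:
    print(f"{r.roi_id}: before={r.nearest_before_s} s, after={r.nearest_after_s} s,"
          f" nearest={r.nearest_abs_s} s, bins={r.bins}")
# p3's only event peaks at 0.4 dF/F: below the 0.5 qualifying rule, so it
# contributes no latency but still counts in the bin denominators.

print()
print(bin_latency_fractions(records).to_string(index=False))
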