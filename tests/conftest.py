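import numpy as np
import pytest

from flysleep.dam import ActivityTrace, LightSchedule
from flysleep.mapping import Marker, MarkerMap


@pytest.fixture
def ld_schedule():
    return LightSchedule(lights_on="08:00", regime=("LD",) * 2)


def make_trace(counts, schedule=None, start_hour=8, fly_id="fly", line_id="line"):
    """Minute-binned trace starting at lights-on unless start_hour says else."""
    from datetime import datetime

    counts = np.asarray(counts, dtype=np.int64)
    n_days = counts.size // 1440
    schedule = schedule or LightSchedule(lights_on="08:00", regime=("LD",) * max(n_days, 1))
    return ActivityTrace(
        fly_id=fly_id,
        line_id=line_id,
        start=datetime(2014, 1, 6, start_hour, 0),
        bin_minutes=1,
        counts=counts,
        schedule=schedule,
    )


def brute_force_bouts(counts, threshold):
    """Independent run-length scan for sleep bouts (the oracle)."""
    res = []
    i, n = 0, len(counts)
    while i < n:
        if counts[i] == 0:
            j = i
            while j < n and counts[j] == 0:
                j += 1
            if j - i >= threshold:
                res.append((i, j - i))
            i = j
        else:
            i += 1
    return res


@pytest.fixture
def marker_map_10():
    """Ten SNP markers spanning 25 Mb / 50 cM of one arm."""
    positions = range(1_000_000, 26_000_000, 2_500_000)
    cms = np.linspace(0.0, 50.0, 10)
    markers = [
        Marker(f"m{i}", "SNP", "3R", pos, float(cm))
        for i, (pos, cm) in enumerate(zip(positions, cms))
    ]
    return MarkerMap(markers, chrom_length_bp=27_000_000)
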