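"""Published summary tables from the cat primary-visual-cortex recordings that
this pipeline targets.

The raw spike trains of those sessions are not publicly deposited, but two of
the study's printed summary tables are sufficient inputs for worked examples
and cross-checks:

* :func:`firing_rate_table` -- mean firing rate (Hz) of the 32 recorded
  channels under each of the six moving-bar stimuli, over the 120 s of
  concatenated trials per stimulus.  Channels 4, 5, and 29 fire far above the
  20 Hz "medium rate" ceiling and are the ones excluded by the outlier
  screen.
* :func:`graph_measure_table` -- the four whole-graph measures (density,
  characteristic path length, global efficiency, global clustering) of the
  Cox connectivity graph estimated for each stimulus.

Values are transcribed at the precision they were printed (rates to 0.1 Hz,
measures to 4 decimals); derived quantities such as correlations of rate
vectors therefore carry rounding error of that magnitude.
"""

from __future__ import annotations

import pandas as pd

STIMULI = [1, 2, 3, 4, 5, 6]

_FIRING_RATES_HZ: dict[int, list[float]] = {
    1: [3.0, 4.1, 8.5, 7.4, 9.0, 7.0],
    2: [4.5, 8.0, 6.5, 5.4, 6.7, 6.2],
    3: [6.3, 7.1, 4.6, 4.8, 6.4, 7.8],
    4: [96.9, 94.1, 118.2, 87.1, 135.5, 106.9],
    5: [18.6, 16.1, 42.9, 30.5, 41.9, 24.1],
    6: [1.6, 2.0, 5.8, 2.7, 6.0, 3.4],
    7: [3.0, 4.0, 5.2, 4.8, 4.2, 3.8],
    8: [8.0, 7.2, 2.1, 1.9, 4.3, 2.8],
    9: [1.0, 0.8, 2.4, 1.1, 5.7, 0.8],
    10: [3.6, 4.3, 7.5, 3.5, 11.5, 5.2],
    11: [2.9, 3.2, 4.0, 3.2, 4.9, 3.4],
    12: [6.4, 5.4, 5.5, 3.9, 9.3, 5.4],
    13: [8.4, 5.8, 7.7, 3.8, 11.0, 9.7],
    14: [6.1, 2.0, 4.0, 1.6, 10.4, 3.5],
    15: [3.8, 4.6, 3.3, 3.8, 8.5, 4.3],
    16: [4.5, 4.1, 6.2, 4.9, 6.7, 6.2],
    17: [2.2, 3.1, 3.3, 3.2, 4.5, 2.9],
    18: [2.3, 2.7, 2.6, 2.4, 3.6, 2.4],
    19: [3.8, 2.9, 3.7, 3.2, 4.8, 2.6],
    20: [4.6, 4.3, 4.7, 3.8, 7.5, 4.1],
    21: [2.7, 3.6, 4.8, 3.8, 5.7, 4.1],
    22: [4.7, 4.5, 4.6, 4.8, 6.2, 5.2],
    23: [2.3, 2.4, 3.1, 2.3, 3.2, 2.8],
    24: [3.5, 4.1, 4.6, 3.3, 4.9, 3.7],
    25: [2.9, 3.9, 4.3, 4.2, 6.2, 4.0],
    26: [2.4, 2.9, 3.7, 2.5, 4.9, 3.7],
    27: [4.7, 5.8, 6.6, 5.4, 8.2, 4.9],
    28: [7.2, 8.3, 6.0, 4.8, 16.7, 4.4],
    29: [33.5, 32.1, 31.5, 28.5, 39.3, 35.7],
    30: [3.6, 5.2, 5.0, 5.1, 6.5, 6.5],
    31: [5.8, 4.5, 2.6, 1.8, 5.2, 7.0],
    32: [9.6, 12.7, 11.1, 8.2, 18.0, 17.4],
}

_GRAPH_MEASURES: dict[int, list[float]] = {
    # stimulus: [density, char_path_length, global_efficiency, global_clustering]
    1: [0.0874, 3.1634, 0.2456, 0.2276],
    2: [0.0764, 2.7747, 0.1871, 0.2213],
    3: [0.1170, 2.8137, 0.3428, 0.3749],
    4: [0.0874, 3.1204, 0.2278, 0.2408],
    5: [0.1429, 2.3377, 0.4041, 0.2715],
    6: [0.0936, 3.0560, 0.2939, 0.2139],
}


def firing_rate_table() -> pd.DataFrame:
    """32 channels x 6 stimuli firing-rate table (Hz)."""
    df = pd.DataFrame(_FIRING_RATES_HZ).T
    df.columns = STIMULI
    df.index.name = "channel"
    return df


def graph_measure_table() -> pd.DataFrame:
    """Per-stimulus whole-graph measures of the estimated connectivity graphs."""
    df = pd.DataFrame(
        _GRAPH_MEASURES,
        index=["density", "char_path_length", "global_efficiency", "global_clustering"],
    ).T
    df.index.name = "stimulus"
    return df
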