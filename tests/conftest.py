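import numpy as np
import pytest

from beatboost import preprocess, synth


@pytest.fixture(scope="session")
def noiseless_record():
    """200 jittered beats of all five classes, zero noise, seed 2."""
    cfg = synth.SynthConfig(n_beats=200, seed=2, noise=synth.NoiseConfig.none())
    record, gt = synth.generate_record(cfg)
    return cfg, record, gt


@pytest.fixture(scope="session")
def noisy_record_500():
    """The default 500-beat record with default noise, seed 3."""
    cfg = synth.SynthConfig(n_beats=500, seed=3)
    record, gt = synth.generate_record(cfg)
    return cfg, record, gt


@pytest.fixture(scope="session")
def denoised_lead_a_500(noisy_record_500):
    _, record, _ = noisy_record_500
    return preprocess.denoise(record.lead(0), record.sampling_rate)


def match_peaks(detected, truth, tol=5):
    """Greedy one-to-one matching of detected to true indices."""
    detected = np.asarray(detected)
    truth = np.asarray(truth)
    used = np.zeros(len(detected), dtype=bool)
    tp = 0
    for t in truth:
        if len(detected) == 0:
            break
        d = np.abs(detected - t)
        d[used] = tol + 1
        j = int(np.argmin(d))
        if d[j] <= tol:
            used[j] = True
            tp += 1
    fp = len(detected) - tp
    fn = len(truth) - tp
    return tp, fp, fn


#: Five-class confusion matrix of the boosted-forest classifier on the
#: optimal feature combination, as printed in the source experiment's
#: results table (rows = true N,S,V,F,Q; columns = predicted).
PRINTED_CONFUSION = np.array(
    [
        [9031, 1, 3, 0, 0],
        [43, 209, 1, 0, 0],
        [20, 0, 765, 0, 0],
        [10, 0, 12, 56, 1],
        [6, 0, 0, 0, 787],
    ]
)

#: The per-class metrics printed alongside that matrix
#: (Se, Sp, +p, Acc in percent).
PRINTED_METRICS = {
    "N": (99.95, 95.86, 99.13, 99.24),
    "S": (82.61, 99.99, 99.52, 99.58),
    "V": (97.45, 99.84, 97.95, 99.67),
    "F": (70.88, 100.0, 100.0, 99.79),
    "Q": (99.24, 99.99, 99.87, 99.94),
}

PRINTED_OVERALL_ACCURACY = 99.11
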