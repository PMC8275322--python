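"""Toy encoder factories used by the external-encoder plugin tests."""

import numpy as np


def mean_encoder(spec):
    """Always emits 5 values: channel means plus two fixed moments."""

    def encode(pixels):
        ch = np.asarray(pixels)[:, :, 0]
        return np.array([ch.mean(), ch.std(), ch.max(), ch.min(), ch.sum()])

    return encode
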