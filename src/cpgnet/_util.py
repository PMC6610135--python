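"""Small internal helpers."""

import numpy as np


def as_seedseq(seed) -> np.random.SeedSequence:
    """Coerce an int, sequence of ints or SeedSequence into a SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)
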