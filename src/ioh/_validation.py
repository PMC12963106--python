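"""Small shared argument checks."""

from __future__ import annotations

import numpy as np


def check_both_classes(labels, name: str = "labels") -> None:
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError(f"{name} must contain both classes")
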