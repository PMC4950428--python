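"""Synthetic pan-genome generation: near-identical mutated copies."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SimulationConfig:
    base_length: int = 1000
    num_sequences: int = 3
    substitution_rate: float = 0.01
    indel_rate: float = 0.001
    seed: int = 0
    alphabet: str = "ACGT"

    def __post_init__(self) -> None:
        if self.base_length < 1:
            raise ValueError("base_length must be positive")
        if self.num_sequences < 1:
            raise ValueError("num_sequences must be positive")
        for name in ("substitution_rate", "indel_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")


def simulate_pangenome(cfg: SimulationConfig) -> list[tuple[str, str]]:
    """One base sequence plus mutated copies, deterministic under the seed.

    Each copy applies per-base substitutions at ``substitution_rate`` and,
    at ``indel_rate`` per base, an insertion or deletion whose length is
    geometric with mean 2.
    """
    rng = np.random.default_rng(cfg.seed)
    letters = list(cfg.alphabet)
    base = "".join(rng.choice(letters, size=cfg.base_length))
    records = [("base", base)]
    for j in range(2, cfg.num_sequences + 1):
        out = []
        i = 0
        while i < len(base):
            r = rng.random()
            if r < cfg.indel_rate:
                length = int(rng.geometric(0.5))
                if rng.random() < 0.5:
                    out.append("".join(rng.choice(letters, size=length)))
                    out.append(base[i])
                    i += 1
                else:
                    i += length  # deletion
            elif r < cfg.indel_rate + cfg.substitution_rate:
                current = base[i]
                choices = [c for c in letters if c != current]
                out.append(str(rng.choice(choices)))
                i += 1
            else:
                out.append(base[i])
                i += 1
        seq = "".join(out)
        if not seq:  # pathological rates on tiny bases
            seq = base[:1]
        records.append((f"copy{j - 1}", seq))
    return records
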