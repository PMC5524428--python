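"""Tunable thresholds for the audit pipeline.

Every knob that the error classifiers and filters consult lives here, with
the defaults used throughout: a 19-bp complexity window with the 2.22
weighted-homopolymer-rate cutoff, the ≥3-SNVs-in-≤50-bp cluster rule, the
5-bp read-end margin with an 80% supporting-read fraction, and the 3-bp
anchor span for paired insertion/deletion base inversions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


@dataclass
class AuditConfig:
    """Flat bag of pipeline parameters; round-trips through key=value files."""

    # simplicity / complexity window
    whr_window: int = 19
    whr_threshold: float = 2.22
    at_rich_fraction: float = 0.8
    gc_rich_fraction: float = 0.8
    dinucleotide_min_units: int = 4

    # SNV cluster rule
    cluster_min_snvs: int = 3
    cluster_span: int = 50

    # peripheral sequence read rule
    peripheral_margin: int = 5
    peripheral_fraction: float = 0.8

    # base inversion rule
    inversion_span: int = 3

    # locus / database matching: allele-aware (chrom,pos,ref,alt) vs
    # position-only (chrom,pos)
    allele_aware: bool = True

    # kit comparison t-test: Student (equal variance) by default
    welch: bool = False

    # pileup rendering
    allowed_pileup_windows: tuple[int, ...] = (81, 201, 501)

    seed: int = 17

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name}={v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "AuditConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, val = line.split("=", 1)
            key, val = key.strip(), val.strip()
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            t = types[key]
            if t == "int":
                kwargs[key] = int(val)
            elif t == "float":
                kwargs[key] = float(val)
            elif t == "bool":
                kwargs[key] = val.lower() in ("1", "true", "yes")
            elif t.startswith("tuple"):
                kwargs[key] = tuple(int(x) for x in val.split(",") if x)
            else:
                kwargs[key] = val
        return cls(**kwargs)


DEFAULT_CONFIG = AuditConfig()
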