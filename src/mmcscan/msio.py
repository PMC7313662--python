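"""ms-format haplotype I/O, YAML run configuration and seed bookkeeping.

The ms dialect used here is the classic one: replicates separated by ``//``,
then ``segsites: S`` and ``positions:`` as fractions of the span, followed
by one 0/1 row per haplotype.  Positions are quantised to 1-bp resolution
against the span on read, so write→read round-trips reproduce base-pair
coordinates exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json

import numpy as np
import yaml

from .engine import HaplotypeMatrix
from .params import (DemographyModel, PsiModel, SelectionModel,
                     SimulationParams)

__all__ = ["write_ms", "read_ms", "read_vcf", "RunConfig", "config_hash"]


class MsParseError(ValueError):
    def __init__(self, msg: str, line: int):
        super().__init__(f"line {line}: {msg}")
        self.line = line


def write_ms(path, matrices: list[HaplotypeMatrix], header: str = "mmcscan",
             meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(header.rstrip("\n") + "\n")
        if meta:
            fh.write("# " + json.dumps(meta, sort_keys=True) + "\n")
        fh.write("\n")
        for m in matrices:
            span = m.span[1] - m.span[0]
            fh.write("//\n")
            fh.write(f"segsites: {m.S}\n")
            if m.S:
                frac = (m.positions - m.span[0]) / span
                fh.write("positions: "
                         + " ".join(f"{x:.10f}" for x in frac) + "\n")
                for row in m.matrix:
                    fh.write("".join("1" if v else "0" for v in row) + "\n")
            fh.write("\n")


def read_ms(path, span: tuple[int, int]) -> list[HaplotypeMatrix]:
    """Parse an ms-format file; positions are mapped back to bp within span."""
    length = span[1] - span[0]
    out: list[HaplotypeMatrix] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        if lines[i].strip() != "//":
            i += 1
            continue
        i += 1
        if i >= n_lines or not lines[i].startswith("segsites:"):
            raise MsParseError("expected 'segsites:' after '//'", i + 1)
        try:
            S = int(lines[i].split(":", 1)[1])
        except ValueError:
            raise MsParseError("bad segsites value", i + 1) from None
        i += 1
        if S == 0:
            out.append(HaplotypeMatrix(
                matrix=np.zeros((0, 0), dtype=np.uint8),
                positions=np.zeros(0, dtype=np.int64), span=span))
            continue
        if i >= n_lines or not lines[i].startswith("positions:"):
            raise MsParseError("expected 'positions:' line", i + 1)
        frac = np.array([float(x) for x in lines[i].split()[1:]])
        if frac.size != S:
            raise MsParseError(
                f"expected {S} positions, got {frac.size}", i + 1)
        pos = span[0] + np.round(frac * length).astype(np.int64)
        pos = np.minimum(pos, span[1] - 1)
        if np.any(np.diff(pos) <= 0):
            raise MsParseError("positions not strictly increasing "
                               "(at 1-bp resolution)", i + 1)
        i += 1
        rows = []
        while i < n_lines and lines[i].strip() and lines[i].strip() != "//":
            row = lines[i].strip()
            if set(row) - {"0", "1"}:
                raise MsParseError("haplotype rows must be 0/1", i + 1)
            if len(row) != S:
                raise MsParseError(
                    f"row length {len(row)} != segsites {S}", i + 1)
            rows.append([int(c) for c in row])
            i += 1
        if not rows:
            raise MsParseError("no haplotype rows in block", i + 1)
        out.append(HaplotypeMatrix(
            matrix=np.array(rows, dtype=np.uint8), positions=pos, span=span))
    return out


def read_vcf(path, span: tuple[int, int] | None = None) -> HaplotypeMatrix:
    """Optional biallelic phased VCF reader (plain-text VCF).

    Multi-allelic or unphased records are rejected with a clear error.
    """
    positions = []
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 10:
                raise ValueError(f"line {ln}: VCF record without genotypes")
            alt = f[4]
            if "," in alt:
                raise ValueError(
                    f"line {ln}: multi-allelic records are not supported")
            gts = []
            for sample in f[9:]:
                gt = sample.split(":", 1)[0]
                if "/" in gt:
                    raise ValueError(
                        f"line {ln}: unphased genotype {gt!r}")
                for a in gt.split("|"):
                    if a not in ("0", "1"):
                        raise ValueError(f"line {ln}: bad allele {a!r}")
                    gts.append(int(a))
            positions.append(int(f[1]) - 1)  # VCF is 1-based
            rows.append(gts)
    if not rows:
        raise ValueError("no variant records in VCF")
    mat = np.array(rows, dtype=np.uint8).T
    pos = np.asarray(positions, dtype=np.int64)
    order = np.argsort(pos, kind="stable")
    if span is None:
        span = (0, int(pos.max()) + 1)
    return HaplotypeMatrix(matrix=np.ascontiguousarray(mat[:, order]),
                           positions=pos[order], span=span)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Validated scenario + scan configuration for the CLI.

    YAML keys: population, demography, selection, psi, scan, abc, seeds.
    """
    params: SimulationParams
    obs_params: SimulationParams
    demography: DemographyModel
    selection: SelectionModel | None
    psi: PsiModel
    window: int
    step: int
    tolerance: float
    level: float
    n_training: int
    n_neutral: int
    n_replicates: int
    seed: int
    outdir: str

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        try:
            popd = dict(raw["population"])
            scan = dict(raw.get("scan", {}))
            abc = dict(raw.get("abc", {}))
            seeds = dict(raw.get("seeds", {}))
        except KeyError as e:
            raise KeyError(f"missing config section: {e.args[0]}") from None
        window = int(scan.get("window", 10_000))
        L_obs = int(popd.pop("L", 100_000))
        base = dict(N=int(popd["N"]), mu=float(popd["mu"]),
                    rho=float(popd.get("rho", float(popd["mu"]) / 1.2)),
                    lam=float(popd.get("lam", 1.0)),
                    n_sample=int(popd.get("n_sample", 40)))
        seed = int(seeds.get("seed", 0))
        params = SimulationParams(L=window, seed=seed, **base)
        obs_params = SimulationParams(L=L_obs, seed=seed, **base)
        dem = dict(raw.get("demography", {}) or {})
        demography = DemographyModel(
            kind=dem.get("kind", "equilibrium"),
            beta=float(dem.get("beta", 1.0)),
            t_b=float(dem.get("t_b", 0.0)),
            duration=dem.get("duration"),
            tau_max=dem.get("tau_max"))
        seld = raw.get("selection")
        selection = None
        if seld:
            if "two_ns" in seld:
                selection = SelectionModel.from_2ns(
                    float(seld["two_ns"]), params.N,
                    dominance=float(seld.get("dominance", 0.5)))
            else:
                selection = SelectionModel(
                    s=float(seld["s"]),
                    position=seld.get("position"),
                    dominance=float(seld.get("dominance", 0.5)))
        psid = dict(raw.get("psi", {}) or {})
        psi = PsiModel(psi=psid.get("psi"),
                       prior_low=float(psid.get("prior_low", 0.004)),
                       prior_high=float(psid.get("prior_high", 0.08)))
        return cls(
            params=params, obs_params=obs_params, demography=demography,
            selection=selection, psi=psi,
            window=window, step=int(scan.get("step", window // 2)),
            tolerance=float(abc.get("tolerance", 0.10)),
            level=float(abc.get("level", 0.99)),
            n_training=int(abc.get("n_training", 2000)),
            n_neutral=int(scan.get("n_neutral", 20)),
            n_replicates=int(scan.get("n_replicates", 20)),
            seed=seed,
            outdir=str(raw.get("outdir", ".")))


def config_hash(cfg: RunConfig) -> str:
    """Short provenance hash embedded in every output file.

    Covers the scientific configuration only — the output directory does
    not change what was computed.
    """
    d = dataclasses.asdict(cfg)
    d.pop("outdir", None)
    blob = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
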