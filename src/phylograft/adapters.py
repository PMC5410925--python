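"""Adapter contracts for external inference engines.

The heavy lifting of production runs — multiple sequence alignment (MAFFT,
MUSCLE), maximum-likelihood / Bayesian tree inference (RAxML, ExaML, PhyML,
ExaBayes), penalized-likelihood dating (treePL) and multispecies-coalescent
clade inference (*BEAST) — is done by external programs.  This module defines
the only thing the pipeline needs to know about them: a command template with
``{input}``/``{output}`` tokens, plus parsing of whatever Newick they return.
The built-in NJ/MPL stand-ins keep the pipeline runnable offline; an adapter
simply replaces the corresponding stage output.
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .trees import Chronogram

__all__ = ["EngineAdapter", "AdapterError"]


class AdapterError(RuntimeError):
    pass


@dataclass(frozen=True)
class EngineAdapter:
    """An external command producing one or more Newick trees.

    ``template`` example: ``"raxmlHPC -s {input} -n run -w {workdir}"``.
    ``output_pattern`` is a glob (relative to the working directory) locating
    the Newick output(s).  The contract: the engine consumes the file we wrote
    (alignment/supermatrix/tree, stage-dependent) and returns trees over
    exactly the input taxa.
    """

    name: str
    template: str
    output_pattern: str = "*.nwk"
    dialect: str = "plain"

    def run(self, input_path: Path, workdir: Path | None = None) -> list[Chronogram]:
        workdir = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="adapter_"))
        workdir.mkdir(parents=True, exist_ok=True)
        cmd = self.template.format(input=str(input_path), workdir=str(workdir), output=str(workdir / "out.nwk"))
        try:
            subprocess.run(shlex.split(cmd), check=True, capture_output=True)
        except FileNotFoundError as exc:
            raise AdapterError(f"{self.name}: executable not found ({exc})") from exc
        except subprocess.CalledProcessError as exc:
            raise AdapterError(
                f"{self.name} failed ({exc.returncode}): {exc.stderr.decode(errors='replace')[:500]}"
            ) from exc
        outputs = sorted(workdir.glob(self.output_pattern))
        if not outputs:
            raise AdapterError(f"{self.name}: no output matching {self.output_pattern!r}")
        trees = []
        for path in outputs:
            with open(path) as fh:
                for line in fh:
                    line = line.strip()
                    if line:
                        trees.append(
                            Chronogram.from_newick(
                                line, support_labels=(self.dialect == "support")
                            )
                        )
        input_taxa = None  # taxon check is the caller's job (formats differ)
        return trees
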