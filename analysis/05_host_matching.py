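"""Match the assembled cyanopodovirus to its host by co-occurrence.

The contig is actively transcribed at all three sites only in October;
an actively infecting phage must have host cells present, so candidate
cyanobacterial ASVs are scored by the fraction of phage-active samples
in which they occur. The Prochlorococcus ASV is absent from the port
(POLA) while the phage is active there, leaving Synechococcus as the
inferred host.

Reads results/survey + results/dynamics, writes results/hosts/.
"""

import json
from pathlib import Path

from phagetrace.pipeline import read_tsv, stage_hosts

OUTDIR = Path("results/hosts")


def main():
    abundance = read_tsv("results/dynamics/abundance_matrix.tsv")
    rna = abundance.loc[[s for s in abundance.index if s.endswith("RNA")]]
    asv = read_tsv("results/survey/asv_rna.tsv")
    meta = json.loads(Path("results/survey/scenario.json").read_text())
    podo = meta["podo_contig"]
    candidates = ["Prochlorococcus_ASV4", "Synechococcus_ASV10"]
    result = stage_hosts(rna, asv[candidates], [podo], OUTDIR, "-")
    for asv_id, score in result[podo]:
        print(f"  {asv_id}: consistency {score:.3f}")
    best = result[podo][0][0]
    print(f"inferred host of {podo}: {best}")
    print(f"outputs under {OUTDIR}/")


if __name__ == "__main__":
    main()
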