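"""OTU inventory bookkeeping for the nematode metabarcoding survey.

The survey's clustering step yielded 145 preliminary nematode OTUs; six
were struck from the list — four grouped off-phylum (with Arthropoda or
Phoronida) because of reference-database errors, and two carried long
insertions in conserved regions consistent with erroneous amplification —
leaving 139 query OTUs.

The excluded ids and a handful of survivors are the published barcode
labels; the remaining survivor ids in :func:`synthetic_preliminary_inventory`
are synthetic stand-ins in the same ``<sample>.SSU<number>`` style, since
the full inventory is not part of this package's inputs. The exclusion
arithmetic (145 − 6 = 139 and the audit log) does not depend on the
filler names.
"""

from __future__ import annotations

#: (otu_id, reason) for the six excluded preliminary OTUs
EXCLUDED_OTUS: tuple[tuple[str, str], ...] = (
    ("HE1.SSU866120", "off-phylum: groups with Arthropoda"),
    ("HE6.SSU382930", "off-phylum: groups with Arthropoda"),
    ("HF6.SSU331569", "off-phylum: groups with Arthropoda"),
    ("TS6.SSU559982", "off-phylum: groups with Phoronida"),
    ("HE6.SSU358113", "long insertion within conserved regions"),
    ("TF5.SSU411806", "long insertion within conserved regions"),
)

#: surviving OTU ids that appear verbatim in the survey's results
KNOWN_SURVIVOR_OTUS: tuple[str, ...] = (
    "TF1.SSU676746",
    "HE3.SSU118424",
    "TS1.SSU284163",
    "HF1.SSU759758",
    "HF5.SSU995414",
    "TF1.SSU698227",
    "TF1.SSU700188",
    "TF6.SSU47996",
)

N_PRELIMINARY = 145
N_FINAL = 139


def synthetic_preliminary_inventory() -> list[str]:
    """The 145-id preliminary OTU list (synthetic stand-in).

    Contains every excluded id and every survivor id known verbatim;
    the rest are deterministic synthetic filler ids in the same naming
    style, so the list always has exactly :data:`N_PRELIMINARY` entries.
    """
    ids = list(KNOWN_SURVIVOR_OTUS) + [e for e, _ in EXCLUDED_OTUS]
    samples = ("HE2", "HF3", "TS4", "TF2")
    k = 0
    while len(ids) < N_PRELIMINARY:
        ids.append(f"{samples[k % len(samples)]}.SSU{100000 + k}")
        k += 1
    assert len(set(ids)) == N_PRELIMINARY
    return sorted(ids)
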