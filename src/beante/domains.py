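"""Fixture peptides for conserved transposon protein domains.

Autonomous transposable elements encode proteins with superfamily-specific
conserved domains (reverse transcriptase for retroelements, transposases for
the cut-and-paste superfamilies, a helicase for Helitrons).  Real annotation
pipelines query a genome with published domain sequences; this package ships
one fixed 180-aa stand-in peptide per superfamily so that the simulator can
plant elements carrying them and the homology scanner has a self-contained
query set.  The peptides are synthetic: random draws from background amino
acid frequencies, fixed once, mutually dissimilar.
"""

from __future__ import annotations

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"

RT_CORE_TY1_COPIA = (
    "SLSPSTELGNDLRMQLNLDSMYQKAGAESTQFIEIFEGFAGLASPKGGMAATVKVGGEDN"
    "KVAGAILPTKEPHAMIELQQYIELEFKAFVTSQDKDYGPGLIVVRPTPLSKPTAKTWWGT"
    "GRGPDIRTAAMVKLAGVNVTESPDPRVISITEMWRNVVELIPYHHAGNLREYGCANDTEL"
)
RT_CORE_TY3_GYPSY = (
    "LVKMSVDQRASVHPFIADDAPIVVDAREREIGSKAIRGDDARSINANQRGSRLAANTSAA"
    "INYEIYGFIHPILDILGEAVIINHAKGLQFVDKQLSHKRVEKDTAFFKTYGPSNTGQTFD"
    "SKKAYSNYMYVSKFSLVASGYFLNQVRQRDYWEQGIIAVLALKVKNEGKILTQTTEILRL"
)
RT_CORE_LINE = (
    "TKTSCVQLTRPLMDFSVRGTESYDDVPFGISSMVCAKKSISEFGNNRFASASPNAAQELT"
    "VLLPAYFIRKFANKSPAEGIFPKSLQLALFFRKSAERIVADVMEEAISDRTCEQLRRSEI"
    "AGRYLGDEYFDCIEAQCERDLLLYRISLLNTFIALPSPKLLEKSACACGNRGNGWYSIIA"
)
TPASE_CACTA = (
    "LGIKVRNMGTTFLRESIGPQPPDAKDHKSKDKNLSRGAQKSLPDSLHTRGRVLAHYLQEE"
    "LTLEGLAPEVGIHVVGCIEKIDLEGILSSYLAYVDVGRDRDESEGTGYGGIPFLTAQVKD"
    "IEETLKFVSDLEIAVPDKLWQVIGLVDARGHLTTMDSSVAQPLFYQREEEGPNLVMNWRL"
)
TPASE_HAT = (
    "ADARVAAGVLTHRATLTIKKDTLLNPLIAVSDGQFAPYTDKMADTSIIRYAVNATIKHHN"
    "KAYDAAETGQIMLVPTCYTKVYTLPLLLYDREIVTEPRQAVKTILGAVGSDNGALKHAQT"
    "SAKKGVPGEFQANYQVAGTTKKQGIQRIKTPEMIVELYVMTEKGPVVIAKVVLCTGDGGQ"
)
TPASE_MULE = (
    "RISFEEGSIEHFPFQMDRVPLSFTETQTRMRDLDQTSKIKRFNSAKRSDLSSASSTEQLY"
    "SEAVYNELSALIEIDMAEKYNRKIEELFMLIDALIFTETKSLEYKLQQYGEAESVNELIS"
    "AMVKKKFAPLSPVYPPEWNMMRRFTPKVNQAPAENDPHQHAYELKEQRNGLPLNLGKEST"
)
TPASE_PIF_HARBINGER = (
    "LWNHHLLPDLGEYSDYIYTMPACVVTEQFVSIRDAYLSNPREGLGMKIILIHSQPFLHRL"
    "VEYTWTIKEISINECEDKTLKHHLEVSFKFPMLLFLLNTKRMIFASGYDLVEQSDKLGNA"
    "FAVPCGIDTTLLFNFYSMICDQCSQVNAAVVFILTVQSGVKDDGEFEAHAAGSVFEPTAL"
)
HELICASE_HELITRON = (
    "FYQLAVLNSPQNQGAAGRLLVAKAQIINKNEDIVVRNEETGKNMVPRKLTDHAQNAQEPF"
    "ATLPVWLRLAILIAIQHAYDKYIDYRETCPFGSALQMRWDDELIMANCYYSAGMTGSTDS"
    "GVGGEARATIQVRTSSSKEFDTPLKDKKPAHPSQCEGMLVAGAACIWCDLNAGVVQLALK"
)

#: superfamily -> fixture domain peptide used both by the simulator (planted
#: coding regions) and by the homology scanner (default query set).
DOMAIN_PEPTIDES: dict[str, str] = {
    "Ty1-copia": RT_CORE_TY1_COPIA,
    "Ty3-gypsy": RT_CORE_TY3_GYPSY,
    "LINE": RT_CORE_LINE,
    "CACTA": TPASE_CACTA,
    "hAT": TPASE_HAT,
    "MULE": TPASE_MULE,
    "PIF/Harbinger": TPASE_PIF_HARBINGER,
    "Helitron": HELICASE_HELITRON,
}

# one fixed codon per amino acid (common plant-usage codons; none is a stop),
# used for deterministic reverse translation of the fixture peptides
CODON_FOR_AA: dict[str, str] = {
    "A": "GCT", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTC",
    "G": "GGA", "H": "CAT", "I": "ATT", "K": "AAG", "L": "CTT",
    "M": "ATG", "N": "AAC", "P": "CCA", "Q": "CAA", "R": "AGA",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAC",
}

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: full synonymous codon sets (standard code, stops excluded)
SYNONYMOUS_CODONS: dict[str, tuple[str, ...]] = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "M": ("ATG",),
    "N": ("AAT", "AAC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
}


def encode_peptide(peptide: str) -> str:
    """Reverse-translate a peptide with the fixed codon table (no stops)."""
    try:
        return "".join(CODON_FOR_AA[aa] for aa in peptide)
    except KeyError as exc:  # pragma: no cover - guarded by fixture content
        raise ValueError(f"cannot encode amino acid {exc}") from exc
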