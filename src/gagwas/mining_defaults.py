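"""Default keyword and indicator vocabularies for abstract mining.

These lists are curated implementation defaults in the schema the pipeline
expects (keyword term variants, non-human subject indicators, medical
condition indicators, an acronym blacklist); they are editable configuration,
not authoritative vocabularies.  Keyword names cover 12 pregnancy-related
candidate themes (4 pregnancy conditions, 4 female-anatomy, 4 fetal-anatomy)
plus 16 unrelated control themes (8 conditions, 8 anatomy) used as a
negative control in enrichment.
"""

from __future__ import annotations

from .mining import KeywordSpec


def _kw(name, terms, klass, exempt=False):
    return KeywordSpec(name=name, terms=tuple(terms), klass=klass,
                       exclusivity_exempt=exempt)


DEFAULT_KEYWORDS: tuple[KeywordSpec, ...] = (
    # pregnancy conditions; "pregnancy" and "gestation" are ubiquitous in the
    # literature, hence exempt from the exclusivity filter
    _kw("preterm", ["preterm", "prematurity"], "pregnancy-condition"),
    _kw("gestation", ["gestation", "gestational"], "pregnancy-condition", exempt=True),
    _kw("parturition", ["parturition", "parturient"], "pregnancy-condition"),
    _kw("pregnancy", ["pregnancy", "pregnancies", "pregnant"],
        "pregnancy-condition", exempt=True),
    # female anatomy
    _kw("cervix", ["cervix", "cervical"], "female-anatomy"),
    _kw("endometrium", ["endometrium", "endometrial"], "female-anatomy"),
    _kw("myometrium", ["myometrium", "myometrial"], "female-anatomy"),
    _kw("uterus", ["uterus", "uterine", "uteri"], "female-anatomy"),
    # fetal anatomy
    _kw("fetus/embryo", ["fetus", "fetal", "foetus", "foetal", "embryo",
                         "embryonic"], "fetal-anatomy", exempt=True),
    _kw("chorion", ["chorion", "chorionic"], "fetal-anatomy"),
    _kw("amnion", ["amnion", "amniotic"], "fetal-anatomy"),
    _kw("placenta", ["placenta", "placental"], "fetal-anatomy"),
    # control conditions (unrelated to pregnancy; exempt by design)
    _kw("ageing", ["ageing", "aging"], "control-condition", exempt=True),
    _kw("asthma", ["asthma", "asthmatic"], "control-condition", exempt=True),
    _kw("diabetes", ["diabetes", "diabetic"], "control-condition", exempt=True),
    _kw("hypertension", ["hypertension", "hypertensive"],
        "control-condition", exempt=True),
    _kw("migraine", ["migraine", "migraines"], "control-condition", exempt=True),
    _kw("epilepsy", ["epilepsy", "epileptic"], "control-condition", exempt=True),
    _kw("glaucoma", ["glaucoma"], "control-condition", exempt=True),
    _kw("eczema", ["eczema"], "control-condition", exempt=True),
    # control anatomy
    _kw("kidney", ["kidney", "renal"], "control-anatomy", exempt=True),
    _kw("liver", ["liver", "hepatic"], "control-anatomy", exempt=True),
    _kw("retina", ["retina", "retinal"], "control-anatomy", exempt=True),
    _kw("pancreas", ["pancreas", "pancreatic"], "control-anatomy", exempt=True),
    _kw("spleen", ["spleen", "splenic"], "control-anatomy", exempt=True),
    _kw("thyroid", ["thyroid"], "control-anatomy", exempt=True),
    _kw("tendon", ["tendon", "tendons"], "control-anatomy", exempt=True),
    _kw("cochlea", ["cochlea", "cochlear"], "control-anatomy", exempt=True),
)


DEFAULT_GENETIC_TERMS: frozenset[str] = frozenset(
    {"gene", "genes", "genomic", "genetic", "gwas"}
)


DEFAULT_NONHUMAN_INDICATORS: frozenset[str] = frozenset(
    {
        "mouse", "mice", "murine", "rat", "rats", "rodent", "rodents",
        "bovine", "cow", "cows", "cattle", "calf", "calves",
        "cat", "cats", "feline", "dog", "dogs", "canine", "puppy",
        "pig", "pigs", "porcine", "swine", "piglet", "piglets",
        "sheep", "ovine", "ewe", "ewes", "lamb", "lambs",
        "goat", "goats", "caprine", "horse", "horses", "equine", "mare",
        "rabbit", "rabbits", "hamster", "hamsters", "gerbil", "ferret",
        "chicken", "chickens", "hen", "hens", "avian", "duck", "goose",
        "turkey", "quail", "pigeon",
        "zebrafish", "medaka", "salmon", "trout", "tilapia",
        "drosophila", "elegans", "nematode", "xenopus", "yeast",
        "macaque", "monkey", "chimpanzee", "baboon", "marmoset",
        "llama", "alpaca", "camel", "donkey", "bison",
    }
)


# ships small; site-specific lists can be built from any vocabulary with
# build_condition_blacklist (common disease suffixes -osis, -itis, -emia, -oma)
DEFAULT_CONDITION_INDICATORS: frozenset[str] = frozenset(
    {
        "listeriosis", "tuberculosis", "toxoplasmosis", "sarcoidosis",
        "fibrosis", "cirrhosis", "amyloidosis", "endometriosis",
        "thrombosis", "necrosis", "salmonellosis", "brucellosis",
        "hepatitis", "dermatitis", "arthritis", "vasculitis", "gastritis",
        "meningitis", "encephalitis", "nephritis", "pancreatitis",
        "bronchitis", "colitis", "cystitis", "thyroiditis",
        "anemia", "anaemia", "leukemia", "leukaemia", "septicemia",
        "septicaemia", "ischemia", "ischaemia", "hyperlipidemia",
        "bacteremia", "viremia", "uremia",
        "neuroblastoma", "melanoma", "carcinoma", "lymphoma", "glioma",
        "sarcoma", "adenoma", "myeloma", "retinoblastoma", "hepatoma",
        "erythema",
    }
)


DEFAULT_DISEASE_SUFFIXES: tuple[str, ...] = ("osis", "itis", "emia", "oma")


#: words that end in a disease suffix but are not conditions
DEFAULT_SUFFIX_ALLOWLIST: frozenset[str] = frozenset(
    {
        "diagnosis", "prognosis", "analysis", "analyses", "hypothesis",
        "apoptosis", "meiosis", "mitosis", "homeostasis", "anastomosis",
        "biosynthesis", "phagocytosis", "endocytosis", "exocytosis",
        "genoma", "aroma", "stroma", "glaucoma",  # glaucoma kept testable
        "academia",
    }
)


DEFAULT_ACRONYM_BLACKLIST: dict[str, tuple[str, ...]] = {
    "SPTB": ("spontaneous preterm birth",),
    "AGA": ("appropriate for gestational age",),
    "FGR": ("fetal growth retardation", "fetal growth restriction"),
}
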