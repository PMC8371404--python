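"""Bundled list of frequent English first names for item construction.

Domains are formed by sampling k distinct names and alphabetizing them, so
the mentioned individual (the one named in the focus answer) is always the
alphabetically first and sits at bit 0 of the state encoding.
"""

FIRST_NAMES = (
    "Aiden", "Amelia", "Ashanti", "Audrey", "Bella", "Benjamin", "Bob",
    "Bryce", "Caleb", "Charlotte", "Chloe", "Dale", "Daniel", "Elijah",
    "Emma", "Ethan", "Grace", "Hannah", "Harper", "Isabella", "Jacob",
    "James", "Jasmine", "Kevin", "Liam", "Lucas", "Mason", "Mia", "Noah",
    "Olivia", "Owen", "Riley", "Ruby", "Skylar", "Sophia", "Tyler",
    "Victoria", "William", "Wyatt", "Zoe",
)
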