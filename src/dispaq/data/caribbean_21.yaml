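# Caribbean regional grouping: the 21 territories with 90,000 or more
# inhabitants in the UN WPP 2012 revision, under the extended Caribbean
# definition (UN Caribbean islands plus Belize and the three Guianas).
# Membership names reconstructed from that rule; synthetic panels attach
# generated series to these ids.
regions:
  Caribbean:
    - Antigua and Barbuda
    - Aruba
    - Bahamas
    - Barbados
    - Belize
    - Cuba
    - Curacao
    - Dominican Republic
    - French Guiana
    - Grenada
    - Guadeloupe
    - Guyana
    - Haiti
    - Jamaica
    - Martinique
    - Puerto Rico
    - Saint Lucia
    - Saint Vincent and the Grenadines
    - Suriname
    - Trinidad and Tobago
    - United States Virgin Islands
notes:
  Caribbean: >-
    Extended Caribbean grouping (islands with >= 90k inhabitants in 2012,
    plus Belize, Guyana, Suriname and French Guiana).
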