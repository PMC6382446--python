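# Synthetic stand-in for a folate-pathway gene list (93 symbols).
# Anchor symbols are real folate-pathway genes; FOLS* fillers pad to the documented size.
MTHFR
TCN2
MTR
MTRR
SLC19A1
FOLR1
FOLR2
DHFR
SHMT1
TYMS
MTHFD1
AHCY
FOLS013
FOLS014
FOLS015
FOLS016
FOLS017
FOLS018
FOLS019
FOLS020
FOLS021
FOLS022
FOLS023
FOLS024
FOLS025
FOLS026
FOLS027
FOLS028
FOLS029
FOLS030
FOLS031
FOLS032
FOLS033
FOLS034
FOLS035
FOLS036
FOLS037
FOLS038
FOLS039
FOLS040
FOLS041
FOLS042
FOLS043
FOLS044
FOLS045
FOLS046
FOLS047
FOLS048
FOLS049
FOLS050
FOLS051
FOLS052
FOLS053
FOLS054
FOLS055
FOLS056
FOLS057
FOLS058
FOLS059
FOLS060
FOLS061
FOLS062
FOLS063
FOLS064
FOLS065
FOLS066
FOLS067
FOLS068
FOLS069
FOLS070
FOLS071
FOLS072
FOLS073
FOLS074
FOLS075
FOLS076
FOLS077
FOLS078
FOLS079
FOLS080
FOLS081
FOLS082
FOLS083
FOLS084
FOLS085
FOLS086
FOLS087
FOLS088
FOLS089
FOLS090
FOLS091
FOLS092
FOLS093
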