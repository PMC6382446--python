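# Synthetic stand-in for a curated mouse neural-tube-defect gene list (221 symbols).
# Anchor symbols are real NTD-associated genes; MNTD* fillers pad to the documented size.
DLC1
ITGB1
APAF1
SHROOM3
PAX3
GRHL3
VANGL1
VANGL2
CELSR1
SCRIB
FZD3
DVL2
PTK7
SFRP1
FREM2
C2CD3
IFT172
MNTD018
MNTD019
MNTD020
MNTD021
MNTD022
MNTD023
MNTD024
MNTD025
MNTD026
MNTD027
MNTD028
MNTD029
MNTD030
MNTD031
MNTD032
MNTD033
MNTD034
MNTD035
MNTD036
MNTD037
MNTD038
MNTD039
MNTD040
MNTD041
MNTD042
MNTD043
MNTD044
MNTD045
MNTD046
MNTD047
MNTD048
MNTD049
MNTD050
MNTD051
MNTD052
MNTD053
MNTD054
MNTD055
MNTD056
MNTD057
MNTD058
MNTD059
MNTD060
MNTD061
MNTD062
MNTD063
MNTD064
MNTD065
MNTD066
MNTD067
MNTD068
MNTD069
MNTD070
MNTD071
MNTD072
MNTD073
MNTD074
MNTD075
MNTD076
MNTD077
MNTD078
MNTD079
MNTD080
MNTD081
MNTD082
MNTD083
MNTD084
MNTD085
MNTD086
MNTD087
MNTD088
MNTD089
MNTD090
MNTD091
MNTD092
MNTD093
MNTD094
MNTD095
MNTD096
MNTD097
MNTD098
MNTD099
MNTD100
MNTD101
MNTD102
MNTD103
MNTD104
MNTD105
MNTD106
MNTD107
MNTD108
MNTD109
MNTD110
MNTD111
MNTD112
MNTD113
MNTD114
MNTD115
MNTD116
MNTD117
MNTD118
MNTD119
MNTD120
MNTD121
MNTD122
MNTD123
MNTD124
MNTD125
MNTD126
MNTD127
MNTD128
MNTD129
MNTD130
MNTD131
MNTD132
MNTD133
MNTD134
MNTD135
MNTD136
MNTD137
MNTD138
MNTD139
MNTD140
MNTD141
MNTD142
MNTD143
MNTD144
MNTD145
MNTD146
MNTD147
MNTD148
MNTD149
MNTD150
MNTD151
MNTD152
MNTD153
MNTD154
MNTD155
MNTD156
MNTD157
MNTD158
MNTD159
MNTD160
MNTD161
MNTD162
MNTD163
MNTD164
MNTD165
MNTD166
MNTD167
MNTD168
MNTD169
MNTD170
MNTD171
MNTD172
MNTD173
MNTD174
MNTD175
MNTD176
MNTD177
MNTD178
MNTD179
MNTD180
MNTD181
MNTD182
MNTD183
MNTD184
MNTD185
MNTD186
MNTD187
MNTD188
MNTD189
MNTD190
MNTD191
MNTD192
MNTD193
MNTD194
MNTD195
MNTD196
MNTD197
MNTD198
MNTD199
MNTD200
MNTD201
MNTD202
MNTD203
MNTD204
MNTD205
MNTD206
MNTD207
MNTD208
MNTD209
MNTD210
MNTD211
MNTD212
MNTD213
MNTD214
MNTD215
MNTD216
MNTD217
MNTD218
MNTD219
MNTD220
MNTD221
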