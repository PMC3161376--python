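assessor_id,study_id,bias_id,nature,action,mean,variance
A1,S1,randomisation,internal,additive,0.042879911300076526,0.01
A1,S1,blinding,internal,additive,0.13395342802421067,0.02
A1,S1,population_relevance,external,proportional,0.8773109167410833,0.02
A1,S2,randomisation,internal,additive,0.041872503236417,0.01
A1,S2,blinding,internal,additive,0.10957416446463186,0.02
A1,S2,population_relevance,external,proportional,0.937134525479599,0.02
A1,S3,randomisation,internal,additive,0.03514009705420411,0.01
A1,S3,blinding,internal,additive,0.11986472390811553,0.02
A1,S3,population_relevance,external,proportional,0.8500087607947444,0.02
A1,S4,randomisation,internal,additive,0.05281141442327945,0.01
A1,S4,blinding,internal,additive,0.05624775762047243,0.02
A1,S4,population_relevance,external,proportional,0.9276542844673024,0.02
A1,S5,randomisation,internal,additive,0.007205525987225965,0.01
A1,S5,blinding,internal,additive,0.14082836335827792,0.02
A1,S5,population_relevance,external,proportional,0.8670698617778967,0.02
A1,S6,randomisation,internal,additive,0.006937653577728041,0.01
A1,S6,blinding,internal,additive,0.056233334534438156,0.02
A1,S6,population_relevance,external,proportional,0.9042947266269638,0.02
A1,S7,randomisation,internal,additive,0.03816408832279273,0.01
A1,S7,blinding,internal,additive,0.10846324344616408,0.02
A1,S7,population_relevance,external,proportional,0.885065475811032,0.02
A1,S8,randomisation,internal,additive,0.08144027718914375,0.01
A1,S8,blinding,internal,additive,0.09219318327393908,0.02
A1,S8,population_relevance,external,proportional,0.8891541022910064,0.02
A2,S1,randomisation,internal,additive,0.006182716707271725,0.01
A2,S1,blinding,internal,additive,0.1480212247349921,0.02
A2,S1,population_relevance,external,proportional,0.9517534070160429,0.02
A2,S2,randomisation,internal,additive,0.07318537445712173,0.01
A2,S2,blinding,internal,additive,0.08543744715593374,0.02
A2,S2,population_relevance,external,proportional,0.9255935918007255,0.02
A2,S3,randomisation,internal,additive,0.02937803612179099,0.01
A2,S3,blinding,internal,additive,0.08960611813544256,0.02
A2,S3,population_relevance,external,proportional,0.9178431555493578,0.02
A2,S4,randomisation,internal,additive,0.0682991084510289,0.01
A2,S4,blinding,internal,additive,0.05220471251002372,0.02
A2,S4,population_relevance,external,proportional,0.8487104782566718,0.02
A2,S5,randomisation,internal,additive,0.06927727656121202,0.01
A2,S5,blinding,internal,additive,0.10987340221444263,0.02
A2,S5,population_relevance,external,proportional,0.9372916413684881,0.02
A2,S6,randomisation,internal,additive,0.022602226108396222,0.01
A2,S6,blinding,internal,additive,0.08680822788545886,0.02
A2,S6,population_relevance,external,proportional,0.8506755800097322,0.02
A2,S7,randomisation,internal,additive,0.06574860810618356,0.01
A2,S7,blinding,internal,additive,0.0984270321294717,0.02
A2,S7,population_relevance,external,proportional,0.9467731757479687,0.02
A2,S8,randomisation,internal,additive,0.04514727930577917,0.01
A2,S8,blinding,internal,additive,0.09983291003312467,0.02
A2,S8,population_relevance,external,proportional,0.8629757403285218,0.02
A3,S1,randomisation,internal,additive,0.01800478211837183,0.01
A3,S1,blinding,internal,additive,0.0704967476827464,0.02
A3,S1,population_relevance,external,proportional,0.8999524603407449,0.02
A3,S2,randomisation,internal,additive,-0.0005973741086514744,0.01
A3,S2,blinding,internal,additive,0.10025737240763702,0.02
A3,S2,population_relevance,external,proportional,0.9216057338929333,0.02
A3,S3,randomisation,internal,additive,0.012907496579782192,0.01
A3,S3,blinding,internal,additive,0.1372745806001351,0.02
A3,S3,population_relevance,external,proportional,0.8916003515747577,0.02
A3,S4,randomisation,internal,additive,0.035794366586326065,0.01
A3,S4,blinding,internal,additive,0.13464029961156662,0.02
A3,S4,population_relevance,external,proportional,0.8725579843448542,0.02
A3,S5,randomisation,internal,additive,0.014696422004003368,0.01
A3,S5,blinding,internal,additive,0.06620591576593117,0.02
A3,S5,population_relevance,external,proportional,0.9169406150136307,0.02
A3,S6,randomisation,internal,additive,0.05745519955591428,0.01
A3,S6,blinding,internal,additive,0.10907402433480981,0.02
A3,S6,population_relevance,external,proportional,0.9001532183860969,0.02
A3,S7,randomisation,internal,additive,0.0421627904862083,0.01
A3,S7,blinding,internal,additive,0.09894555272298225,0.02
A3,S7,population_relevance,external,proportional,0.8919776789691227,0.02
A3,S8,randomisation,internal,additive,0.04321315253229051,0.01
A3,S8,blinding,internal,additive,0.0746865353445465,0.02
A3,S8,population_relevance,external,proportional,0.8554603653645285,0.02
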