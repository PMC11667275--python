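"f0","f1","f2","f3","f4","f5","f6","f7"
0.485428584528,0.518933915691,0.490105581893,0.535347021288,0.525300755075,0.584656209777,0.629924500394,0.60138704615
0.51004186452,0.518341685145,0.525695392216,0.559380557171,0.564359304754,0.563372026465,0.634705414071,0.647969622233
0.498875737593,0.495048952228,0.546552229866,0.524964157636,0.604950255128,0.526898017136,0.601701079423,0.584136505432
0.473371990301,0.46724034056,0.47966948639,0.544172878741,0.572893860505,0.580896010631,0.61325946404,0.609471382313
0.505534703037,0.498868631404,0.563011122392,0.586064842746,0.586966661826,0.611200993883,0.696534724531,0.665932467747
0.475979813779,0.485967706647,0.511489641894,0.596017628481,0.541257629273,0.596284800036,0.655040609401,0.621871263205
0.430064581625,0.490604189866,0.504495372186,0.574381063763,0.556340205202,0.595716769592,0.603180031261,0.635691083367
0.44698973617,0.545507035821,0.549028324654,0.554418430805,0.535273517135,0.590105862971,0.612227237624,0.632854415932
0.480449162845,0.541719554012,0.572667938325,0.565591641359,0.584283748266,0.639551984911,0.671446488664,0.676951769832
0.472329851922,0.53876564995,0.56832567927,0.530313255052,0.585019414171,0.604381875013,0.601997401364,0.618185723171
0.512079007978,0.505904924568,0.534533752077,0.594341391076,0.611382648627,0.616437953107,0.637175644797,0.663071582528
0.456212579959,0.468216261236,0.505279840997,0.549456551227,0.582197833576,0.56695764651,0.601880293108,0.664782674442
0.468275500964,0.470852038777,0.509516000333,0.550243522638,0.499088300476,0.576604288275,0.61480124477,0.593938761651
0.516418561307,0.4810906071,0.529138809078,0.499434445822,0.574048217302,0.590939458452,0.584787553299,0.601346698639
0.489158452109,0.568463845335,0.538660864598,0.582718742469,0.579246162812,0.619731479767,0.582953673901,0.669707622412
0.516442282266,0.49964612644,0.511078578738,0.57628725363,0.591852361214,0.593372981396,0.575173700282,0.637502542841
0.469323742663,0.529581737933,0.531057012169,0.524533181225,0.613558190648,0.606902315399,0.589486041315,0.665951298185
0.501257160675,0.512756201998,0.561040499477,0.56892563018,0.543919426034,0.609890500637,0.627952634659,0.646574297965
0.446690073784,0.514471157634,0.577685265993,0.539652359149,0.539837491361,0.573706435999,0.59096913509,0.651701288453
0.469775681092,0.50581960998,0.564254470499,0.539830074974,0.573350857409,0.602590902584,0.657753579181,0.622152065472
0.506905303744,0.496937780443,0.501262492725,0.53779444661,0.526208936595,0.536674680083,0.638096465297,0.631074691811
0.446460362492,0.509850372848,0.521853358183,0.551680422637,0.609448702986,0.561938304935,0.596568909666,0.672214388121
0.477726528031,0.472769483684,0.475711425306,0.525400465949,0.565387322109,0.537895668371,0.60234256386,0.606064028292
0.475084696068,0.501247507853,0.497360301057,0.536002204674,0.57679464122,0.516737860582,0.585450247373,0.590965446427
0.469229793605,0.488848746211,0.531305729772,0.582245787816,0.551900635623,0.569565505986,0.600942277864,0.612917918838
0.473602314453,0.500994542939,0.583597636546,0.513164007493,0.616158857815,0.633978109244,0.64389733918,0.665354141373
0.487476362827,0.471146263603,0.503606807461,0.540753283506,0.592321381698,0.581328341843,0.631637961095,0.586345094717
0.494083541517,0.542315782598,0.54041024034,0.587645682544,0.604959202687,0.623443150781,0.632439948896,0.675978564077
0.519040718722,0.576307195703,0.500569921169,0.589959505553,0.604992996628,0.645754610001,0.669415341879,0.643975421568
0.477025535672,0.498255450524,0.510106787326,0.527109419298,0.563787955843,0.613577474981,0.574988828058,0.646332888961
0.509089181008,0.493482704368,0.492044999442,0.499501177705,0.544228664842,0.588511174297,0.612607215039,0.581210827821
0.454362777401,0.490173222649,0.490904181873,0.539239466156,0.548240998139,0.610702064735,0.666261342733,0.606434466413
0.462695925857,0.546371931889,0.515577044982,0.602864147539,0.581001118563,0.611373277209,0.635125650262,0.617420143674
0.480381593449,0.506030683289,0.522557430248,0.509757734837,0.5823846992,0.574855318069,0.650932631758,0.625382944169
0.475320650539,0.485170271809,0.475882868457,0.564483277576,0.592301739589,0.575277895515,0.612011222226,0.646779478641
0.533398967713,0.550574531462,0.509980175715,0.560416709455,0.567657093474,0.582229265676,0.654724218905,0.664101116873
0.517188056216,0.527581812088,0.593918207213,0.561912028181,0.586091934064,0.59142804913,0.633080205494,0.655951247067
0.487413253262,0.543984778825,0.497061352678,0.525974350935,0.613224320425,0.591361999561,0.616486924081,0.647131406163
0.532573399873,0.524924598373,0.516547062656,0.557718143561,0.572821564489,0.636154365094,0.61775233761,0.670958118161
0.441283975251,0.467908153253,0.566462976689,0.577425260328,0.547653668264,0.635123302186,0.62445111693,0.617972433572
0.464806354403,0.473635136312,0.603181099858,0.568467843195,0.583406698295,0.567911429143,0.601562641297,0.670650240341
0.445432191409,0.535893503981,0.487072137184,0.584746754295,0.58444540261,0.598335133555,0.628405857394,0.655236378416
0.45139323004,0.529714311544,0.500856304451,0.564096101034,0.558103952265,0.554962848462,0.628805458244,0.640901925547
0.445912019606,0.499566245139,0.536871743279,0.562136342058,0.609434554566,0.611284739941,0.628349570314,0.663307390133
0.4752291384,0.474618387915,0.549323567819,0.575580785692,0.575508829758,0.574783172046,0.59348615497,0.635343487913
0.463079357997,0.531613295877,0.492314238838,0.552991879755,0.585032132543,0.54342314999,0.623218782784,0.689988438122
0.438226574339,0.472081094797,0.517833232117,0.567617319022,0.585646026734,0.617773552328,0.606620426542,0.642808496529
0.456766585773,0.483297276344,0.549216092756,0.545277773095,0.635812365347,0.586065390027,0.644229381125,0.643340062656
0.469283173045,0.503324951329,0.521393693167,0.536922462036,0.553309137666,0.568091210755,0.556727839272,0.61312019118
0.516264906069,0.506327892238,0.530935695103,0.545352283356,0.538614122192,0.586061805148,0.625219875353,0.635802712282
0.539252196213,0.511483536317,0.532551387974,0.583029405989,0.623873699427,0.591449728883,0.5786727187,0.62604449978
0.582444019546,0.523229290693,0.516796574761,0.543952389454,0.587897568319,0.635553224762,0.610140819946,0.650271232414
0.479050292299,0.503971173056,0.511361317002,0.561842507009,0.567226190642,0.584618575607,0.645912346971,0.637979537805
0.446366743568,0.533525176744,0.514389056981,0.540474602202,0.600848265858,0.600623813794,0.636109276182,0.651565999563
0.417006107115,0.499644118544,0.525415835324,0.573279823634,0.527065692355,0.600255423512,0.595183759138,0.643224404553
0.466443950762,0.501026442138,0.493841642729,0.551711288376,0.524320336806,0.611812560589,0.563494731898,0.610046676089
0.459253934351,0.455588143457,0.541601385381,0.598240766548,0.537408713789,0.592613222233,0.547944335239,0.674341139093
0.454837705512,0.489901124679,0.540100165508,0.557086602058,0.543037905984,0.548683577561,0.591967902617,0.654487663191
0.4892362268,0.505846449573,0.553940368352,0.533047881961,0.608628862078,0.649772315237,0.704937626381,0.668305537987
0.503543335109,0.498507025916,0.560749845158,0.572396419951,0.612693631951,0.617143663974,0.658065727166,0.65799506749
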