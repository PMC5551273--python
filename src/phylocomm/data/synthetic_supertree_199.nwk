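((t001,t002,(t003,t004,(t005,t006,t007)),(t008,(t009,t010),t011,t012,t013,((t014,(t015,t016),t017,t018,t019,t020),t021),(t022,t023,t024,t025,t026,t027)),(((((t028,((t029,t030,(t031,t032,t033)),(t034,t035))),t036,(t037,t038,t039,t040,t041,t042,t043,t044,t045)),((t046,t047,t048,(t049,t050,t051,t052)),(t053,t054,(t055,((t056,t057),t058),(t059,t060,t061,t062,t063,t064),(t065,t066)),t067))),(t068,t069,(t070,t071,t072),(t073,(t074,t075),(t076,t077,t078,t079),t080,(t081,t082),t083,(t084,t085),t086,t087),t088,t089,((t090,t091,t092),t093,(t094,(t095,t096),t097),(t098,t099,((((t100,t101),t102),t103,t104),t105)),(t106,(t107,t108,t109))),((t110,t111),(t112,t113),(((t114,t115),t116,t117),(t118,(t119,t120))),t121,(t122,t123)),((t124,(t125,(t126,t127),(t128,t129)),t130,t131),t132,(((t133,t134),t135),t136,t137,t138),t139,t140,t141,t142),t143,((t144,t145,t146,t147),t148)),(t149,t150),(t151,t152),t153),(t154,t155,t156),t157,t158),(t159,t160,t161,t162,t163,t164),t165,t166,t167,t168,t169,t170,t171),t172,(((t173,t174,t175,t176),t177,t178,t179,t180),t181,t182,(t183,t184),t185,(t186,t187),t188,(t189,t190),t191),(t192,t193),((t194,t195),t196,(t197,t198)),t199);
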